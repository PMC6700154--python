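"""Folding free energies and per-residue decompositions.

The global effective folding free energy of a structure under a potential
table is the half-sum of the table value over all ordered residue pairs more
than one position apart:

    dW_mu(S, C)   = 1/2 * sum_{i,j: |i-j|>1} dW_mu(s_i, [s_j,] d_ij)
    dG_mu^i(S, C) = 1/2 * sum_{j: |i-j|>1}   dW_mu(s_i, [s_j,] d_ij)

so the per-residue contributions sum exactly to the global energy. Energies
are effective statistical quantities in kcal/mol units; they carry no claim
of experimental transferability. Leave-one-out potentials are built by
subtracting a protein's raw counts before smoothing and re-thresholding,
which reproduces full recomputation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aa import AA_INDEX
from .contact_counts import PairCounts, _structure_pairs, smooth_counts
from .potentials import COUNT_THRESHOLD, KBT_ROOM, PotentialTable, derive_potential
from .structure_io import LabeledStructure

ENERGY_COLUMNS = ("dg_sd_tm", "dg_sds_tm", "dg_sd_em", "dg_sds_em")


@dataclass
class EnergyProfile:
    """Per-residue energy contributions under the four potential flavors.

    ``frame`` columns: chain, seq_index, aa, region, dg_sd_tm, dg_sds_tm,
    dg_sd_em, dg_sds_em (kcal/mol). Column sums equal the corresponding
    global folding energies by construction.
    """

    structure_id: str
    frame: pd.DataFrame

    def global_energy(self, flavor: str, region: str) -> float:
        return float(self.frame[f"dg_{flavor}_{region.lower()}"].sum())

    def features(self) -> np.ndarray:
        return self.frame[list(ENERGY_COLUMNS)].to_numpy()


def _check_policy(structure_or_flag: bool, table: PotentialTable) -> None:
    want = bool(structure_or_flag)
    have = bool(table.provenance.get("inter_chain", False))
    if want != have:
        raise ValueError(
            "pairing policy mismatch: table was derived with "
            f"inter_chain={have} but energies requested with inter_chain={want}"
        )


def _pair_terms(
    structure: LabeledStructure, table: PotentialTable, inter_chain: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eligible pair index arrays (i, j) and the per-pair unordered energy."""
    ii, jj, _, bins = _structure_pairs(structure, table.scheme, inter_chain)
    aas = np.array([AA_INDEX[r.aa] for r in structure.residues])
    if table.flavor == "sds":
        w = table.values[aas[ii], aas[jj], bins]
        return ii, jj, w
    if table.flavor == "sd":
        # ordered double sum halves to the mean of the two endpoint terms
        w = 0.5 * (table.values[aas[ii], bins] + table.values[aas[jj], bins])
        return ii, jj, w
    raise ValueError(f"energies support flavors 'sd' and 'sds', not {table.flavor!r}")


def folding_energy(
    structure: LabeledStructure,
    table: PotentialTable,
    inter_chain: bool = False,
) -> float:
    """Global effective folding free energy (kcal/mol) under one table."""
    if len(structure.residues) < 3:
        raise ValueError("folding energy needs at least 3 residues")
    _check_policy(inter_chain, table)
    _, _, w = _pair_terms(structure, table, inter_chain)
    return float(w.sum())


def per_residue_energies(
    structure: LabeledStructure,
    tables: dict[tuple[str, str], PotentialTable],
    inter_chain: bool = False,
) -> EnergyProfile:
    """Per-residue contributions under {sd, sds} x {TM, EM} tables.

    Pair sums run over all partners in the structure regardless of the
    partner's region label: the localization step scores every residue under
    both the TM and the EM tables.
    """
    if len(structure.residues) < 3:
        raise ValueError("per-residue energies need at least 3 residues")
    n = len(structure.residues)
    data = {
        "chain": [r.chain_id for r in structure.residues],
        "seq_index": [r.seq_index for r in structure.residues],
        "aa": [r.aa for r in structure.residues],
        "region": [r.region for r in structure.residues],
    }
    aas = np.array([AA_INDEX[r.aa] for r in structure.residues])
    for (flavor, region), table in tables.items():
        _check_policy(inter_chain, table)
        ii, jj, _, bins = _structure_pairs(structure, table.scheme, inter_chain)
        dg = np.zeros(n)
        if flavor == "sds":
            w = table.values[aas[ii], aas[jj], bins]
            np.add.at(dg, ii, 0.5 * w)
            np.add.at(dg, jj, 0.5 * w)
        elif flavor == "sd":
            np.add.at(dg, ii, 0.5 * table.values[aas[ii], bins])
            np.add.at(dg, jj, 0.5 * table.values[aas[jj], bins])
        else:
            raise ValueError(f"unsupported flavor {flavor!r}")
        data[f"dg_{flavor}_{region.lower()}"] = dg
    return EnergyProfile(structure.structure_id, pd.DataFrame(data))


def loo_potentials(
    all_counts: PairCounts,
    held_out: str,
    flavor: str,
    kbt: float = KBT_ROOM,
    threshold: float = COUNT_THRESHOLD,
    threshold_on: str = "raw",
) -> PotentialTable:
    """Potential with one protein's raw counts removed before smoothing.

    ``all_counts`` must be raw pooled counts carrying per-protein sub-counts.
    The held-out protein's raw contribution is subtracted, then smoothing and
    the occurrence threshold are re-applied; this equals deriving from a
    dataset rebuilt without that protein, bin for bin.
    """
    if all_counts.per_protein is None:
        raise ValueError("counts lack per-protein sub-counts")
    if held_out not in all_counts.per_protein:
        raise KeyError(f"unknown structure_id {held_out!r}")
    reduced = all_counts.subtract(all_counts.per_protein[held_out])
    smoothed = smooth_counts(reduced)
    guard = reduced if threshold_on == "raw" else None
    table = derive_potential(smoothed, flavor, kbt, threshold, guard_counts=guard)
    table.provenance["excluded"] = (held_out,)
    table.provenance["dataset_size"] = len(all_counts.per_protein) - 1
    return table
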