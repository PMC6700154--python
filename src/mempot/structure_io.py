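"""Structure parsing, side-chain geometric centers and TM/EM region labels.

The method works on one interaction site per residue: the unweighted centroid
of its side-chain heavy atoms (CA for glycine). This module turns a PDB or
mmCIF text into a :class:`LabeledStructure` of such sites, attaches
transmembrane / extramembrane region labels from a segment annotation table,
and estimates per-type side-chain radii used by group potentials.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .aa import AA_ORDER, BACKBONE_ATOMS, DEFAULT_RADII, ONE_TO_THREE, one_letter

logger = logging.getLogger(__name__)

TM = "TM"
EM = "EM"
UNASSIGNED = "UNASSIGNED"

TOPOLOGY_CLASSES = ("alpha_helical", "beta_barrel", "monotopic", "unknown")


class StructureFormatError(ValueError):
    """Raised when a structure text cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed structure contains no standard residues."""


class AnnotationError(ValueError):
    """Raised for inconsistent or unusable region annotations."""


@dataclass
class Residue:
    """A residue reduced to its side-chain geometric center.

    ``seq_index`` is 1-based and consecutive within each chain (insertion
    codes are flattened). ``atoms`` optionally retains the heavy-atom detail
    used for radius estimation.
    """

    chain_id: str
    seq_index: int
    aa: str
    center: np.ndarray
    region: str = UNASSIGNED
    side_label: str | None = None
    ca: np.ndarray | None = None
    atoms: list[tuple[str, np.ndarray]] | None = None
    center_is_fallback: bool = False
    author_seq_id: int | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not np.all(np.isfinite(self.center)):
            raise ValueError(f"non-finite side-chain center for {self.aa}{self.seq_index}")
        if self.aa not in AA_ORDER:
            raise ValueError(f"non-canonical amino acid type {self.aa!r}")


@dataclass
class LabeledStructure:
    structure_id: str
    residues: list[Residue]
    topology_class: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise EmptyStructureError(
                f"{self.structure_id}: a structure needs at least 2 residues"
            )
        if self.topology_class not in TOPOLOGY_CLASSES:
            raise ValueError(f"unknown topology class {self.topology_class!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def region_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.residues:
            out[r.region] = out.get(r.region, 0) + 1
        return out


@dataclass(frozen=True)
class Segment:
    structure_id: str
    chain_id: str
    start: int
    end: int
    region: str
    side_label: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"segment start {self.start} > end {self.end}")
        if self.region not in (TM, EM):
            raise AnnotationError(f"segment region must be TM or EM, got {self.region!r}")


@dataclass
class RegionAnnotation:
    """OPM-style segment table: 1-based inclusive residue ranges per chain."""

    records: list[Segment] = field(default_factory=list)

    def for_structure(self, structure_id: str) -> list[Segment]:
        return [s for s in self.records if s.structure_id == structure_id]

    @classmethod
    def from_tsv(cls, text: str) -> "RegionAnnotation":
        """Read the TSV interchange format.

        Columns: ``structure_id chain start end region side`` with
        ``region`` in {TM, EM} and ``side`` in {in, out, -}.
        """
        records = []
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        for ln in lines:
            parts = ln.split("\t") if "\t" in ln else ln.split()
            if parts[0] == "structure_id":
                continue
            sid, chain, start, end, region = parts[:5]
            side = parts[5] if len(parts) > 5 else "-"
            records.append(
                Segment(
                    structure_id=sid,
                    chain_id=chain,
                    start=int(start),
                    end=int(end),
                    region=region,
                    side_label=None if side in ("-", "") else
                    {"in": "intracellular", "out": "extracellular"}.get(side, side),
                )
            )
        return cls(records)

    def to_tsv(self) -> str:
        rows = ["structure_id\tchain\tstart\tend\tregion\tside"]
        for s in self.records:
            side = {"intracellular": "in", "extracellular": "out"}.get(
                s.side_label or "-", s.side_label or "-"
            )
            rows.append(f"{s.structure_id}\t{s.chain_id}\t{s.start}\t{s.end}\t{s.region}\t{side}")
        return "\n".join(rows) + "\n"


@dataclass
class RadiusTable:
    """Side-chain radius (Å) per amino-acid type; Gly is 0 by convention."""

    radii: dict[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in AA_ORDER if a not in self.radii]
        if missing:
            raise ValueError(f"radius table is missing entries for {missing}")
        if any(v < 0 for v in self.radii.values()):
            raise ValueError("radii must be non-negative")
        if self.radii["G"] != 0.0:
            raise ValueError("Gly radius must be 0 by convention")

    def __getitem__(self, aa: str) -> float:
        return self.radii[aa]


def default_radius_table() -> RadiusTable:
    return RadiusTable(dict(DEFAULT_RADII))


def _is_hydrogen(atom_name: str) -> bool:
    name = atom_name.strip().lstrip("0123456789")
    return name.startswith("H") or name.startswith("D")


def compute_side_chain_center(
    residue_atoms: list[tuple[str, np.ndarray]], aa: str | None = None
) -> np.ndarray:
    """Unweighted mean of side-chain heavy-atom coordinates.

    Gly (or any residue without side-chain heavy atoms) falls back to CA.
    """
    center, _ = _side_chain_center(residue_atoms, aa)
    return center


def _side_chain_center(
    residue_atoms: list[tuple[str, np.ndarray]], aa: str | None = None
) -> tuple[np.ndarray, bool]:
    heavy = [
        (name.strip().upper(), np.asarray(xyz, dtype=float))
        for name, xyz in residue_atoms
        if not _is_hydrogen(name)
    ]
    if not heavy:
        raise ValueError("residue has no heavy atoms")
    side = [xyz for name, xyz in heavy if name not in BACKBONE_ATOMS]
    ca = [xyz for name, xyz in heavy if name == "CA"]
    if aa == "G" or not side:
        if not ca:
            if aa == "G" and side:
                return np.mean(side, axis=0), True
            raise ValueError("no side-chain atoms and no CA to fall back on")
        return ca[0], aa != "G"
    return np.mean(side, axis=0), False


def _load_atom_array(text: str):
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    stripped = text.lstrip()
    try:
        if stripped.startswith("data_"):
            cif = pdbx.CIFFile.read(io.StringIO(text))
            return pdbx.get_structure(cif, model=1, altloc="occupancy")
        pdb_file = pdb.PDBFile.read(io.StringIO(text))
        return pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        raise StructureFormatError(f"cannot parse structure text: {exc}") from exc


def parse_structure(
    structure_text: str,
    structure_id: str,
    keep_atoms: bool = False,
    topology_class: str = "unknown",
) -> LabeledStructure:
    """Parse PDB (or mmCIF) text into a LabeledStructure with UNASSIGNED regions.

    One Residue per standard amino acid; MSE/SEC map to Met/Cys, other hetero
    residues are skipped. altLoc conformers are resolved to the highest
    occupancy; insertion codes collapse into the consecutive ``seq_index``.
    Residues whose side-chain atoms are all missing use CA as a flagged
    fallback center; residues with no heavy atoms at all are dropped.
    """
    atoms = _load_atom_array(structure_text)
    if atoms is None or atoms.array_length() == 0:
        raise EmptyStructureError(f"{structure_id}: no atoms parsed")

    residues: list[Residue] = []
    chain_counters: dict[str, int] = {}
    # group atoms by (chain, author residue id, insertion code) in file order
    keys = list(
        zip(
            atoms.chain_id,
            atoms.res_id,
            atoms.ins_code if "ins_code" in atoms.get_annotation_categories() else [""] * atoms.array_length(),
        )
    )
    order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(idx)

    for key in order:
        idxs = groups[key]
        res_name = atoms.res_name[idxs[0]]
        aa = one_letter(res_name)
        if aa is None:
            continue
        chain = str(key[0])
        atom_list = [
            (str(atoms.atom_name[i]), atoms.coord[i])
            for i in idxs
            if str(atoms.element[i]).upper() not in ("H", "D")
        ]
        if not atom_list:
            logger.warning(
                "%s: dropping %s %s%s with no resolvable heavy atoms",
                structure_id, res_name, chain, key[1],
            )
            continue
        try:
            center, fallback = _side_chain_center(atom_list, aa)
        except ValueError:
            logger.warning(
                "%s: dropping %s %s%s (no usable atoms)", structure_id, res_name, chain, key[1]
            )
            continue
        if fallback:
            logger.warning(
                "%s: %s %s%s has no side-chain atoms; using CA as center",
                structure_id, res_name, chain, key[1],
            )
        chain_counters[chain] = chain_counters.get(chain, 0) + 1
        ca = next((xyz for name, xyz in atom_list if name.strip().upper() == "CA"), None)
        residues.append(
            Residue(
                chain_id=chain,
                seq_index=chain_counters[chain],
                aa=aa,
                center=center,
                ca=None if ca is None else np.asarray(ca, dtype=float),
                atoms=atom_list if keep_atoms else None,
                center_is_fallback=fallback,
                author_seq_id=int(key[1]),
            )
        )

    if not residues:
        raise EmptyStructureError(f"{structure_id}: no standard residues found")
    return LabeledStructure(structure_id, residues, topology_class=topology_class)


def assign_regions(
    structure: LabeledStructure,
    annotation: RegionAnnotation,
    strict: bool = False,
) -> LabeledStructure:
    """Label residues TM/EM from segment annotations.

    Residues not covered by any segment default to EM: membrane proteins are
    annotated by their membrane-embedded segments and the remainder is
    extramembrane by construction. With ``strict=True`` uncovered residues
    (or a structure with no annotation records) raise instead.
    """
    segments = annotation.for_structure(structure.structure_id)
    if strict and not segments:
        raise AnnotationError(f"no annotation records for {structure.structure_id}")

    by_chain: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chain.setdefault(seg.chain_id, []).append(seg)
    chain_ids = set(structure.chain_ids)
    for chain, segs in by_chain.items():
        if chain not in chain_ids:
            raise AnnotationError(
                f"{structure.structure_id}: segment references missing chain {chain!r}"
            )
        segs = sorted(segs, key=lambda s: (s.start, s.end))
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"{structure.structure_id}/{chain}: overlapping segments "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )

    new_residues = []
    for r in structure.residues:
        region, side = EM, None
        covered = False
        for seg in by_chain.get(r.chain_id, ()):
            if seg.start <= r.seq_index <= seg.end:
                region, side = seg.region, seg.side_label
                covered = True
                break
        if strict and not covered:
            raise AnnotationError(
                f"{structure.structure_id}: residue {r.chain_id}{r.seq_index} "
                "not covered by any segment (strict mode)"
            )
        new_residues.append(replace(r, region=region, side_label=side))
    return LabeledStructure(
        structure.structure_id, new_residues, topology_class=structure.topology_class
    )


def write_pdb(structure: LabeledStructure) -> str:
    """Serialize residues as minimal PDB text that round-trips through
    :func:`parse_structure` (CA at the stored CA or center; CB pseudo-atom at
    the side-chain center for non-Gly residues)."""
    lines = []
    serial = 1
    for r in structure.residues:
        res3 = ONE_TO_THREE[r.aa]
        ca = r.center if r.ca is None else r.ca
        records = [("N", ca + np.array([-0.5, 0.4, -0.9]), "N"),
                   ("CA", ca, "C"),
                   ("C", ca + np.array([0.6, -0.4, 0.8]), "C")]
        if r.aa != "G":
            records.append(("CB", r.center, "C"))
        for name, xyz, element in records:
            lines.append(
                f"ATOM  {serial:>5} {name:<4} {res3:>3} {r.chain_id:1}{r.seq_index:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def estimate_residue_radii(
    structures: list[LabeledStructure],
    defaults: RadiusTable | None = None,
) -> RadiusTable:
    """Per-type side-chain radius: mean over occurrences of the mean distance
    of side-chain heavy atoms to the side-chain geometric center.

    Requires structures parsed with ``keep_atoms=True``. Types without any
    occurrence fall back to the shipped defaults; Gly is 0 by convention.
    """
    if not structures:
        raise ValueError("estimate_residue_radii needs at least one structure")
    defaults = defaults or default_radius_table()
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for st in structures:
        for r in st.residues:
            if r.atoms is None or r.aa == "G":
                continue
            side = [
                np.asarray(xyz, float)
                for name, xyz in r.atoms
                if name.strip().upper() not in BACKBONE_ATOMS and not _is_hydrogen(name)
            ]
            if not side:
                continue
            pts = np.array(side)
            centroid = pts.mean(axis=0)
            spread = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
            sums[r.aa] = sums.get(r.aa, 0.0) + spread
            counts[r.aa] = counts.get(r.aa, 0) + 1
    radii = {}
    for a in AA_ORDER:
        if a == "G":
            radii[a] = 0.0
        elif a in counts:
            radii[a] = sums[a] / counts[a]
        else:
            radii[a] = defaults[a]
    return RadiusTable(radii)
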