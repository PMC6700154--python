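"""Synthetic membrane-protein datasets with controllable statistics.

The generator emulates the statistical structure the potentials feed on:
contiguous transmembrane segments (ideal helices spanning a virtual slab, or
strands on a cylinder for barrels) connected by extramembrane loops,
region-dependent amino-acid composition (aliphatic/aromatic enrichment in
TM, charged/polar enrichment in EM), and planted distance-specific group
contacts (e.g. salt bridges near 4 Å) whose frequency differs between
regions. Planting works by rejection-resampling residue *types* at
pre-selected spatially close position pairs; the geometry is never distorted
to force a contact. Structures are emitted as standard PDB text with the
side-chain geometric center written as a CB pseudo-atom, so they round-trip
through the parser.

There is no physical realism here (no lipids, no minimization, no rotamers):
only the statistical features the method consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .aa import AA_ORDER, GROUP_MEMBERS
from .structure_io import (
    EM,
    TM,
    LabeledStructure,
    RegionAnnotation,
    Segment,
    assign_regions,
    parse_structure,
)

# Region-conditional compositions, qualitatively matching the observed
# contrast: aliphatic (I/V/L) and aromatic residues enriched in the membrane,
# charged and polar residues enriched outside.
TM_COMPOSITION = {
    "A": 0.10, "C": 0.02, "D": 0.02, "E": 0.03, "F": 0.08, "G": 0.08,
    "H": 0.02, "I": 0.09, "K": 0.02, "L": 0.14, "M": 0.04, "N": 0.03,
    "P": 0.03, "Q": 0.02, "R": 0.02, "S": 0.05, "T": 0.05, "V": 0.09,
    "W": 0.03, "Y": 0.04,
}
EM_COMPOSITION = {
    "A": 0.07, "C": 0.01, "D": 0.06, "E": 0.07, "F": 0.04, "G": 0.07,
    "H": 0.02, "I": 0.05, "K": 0.07, "L": 0.08, "M": 0.02, "N": 0.05,
    "P": 0.05, "Q": 0.04, "R": 0.06, "S": 0.07, "T": 0.06, "V": 0.06,
    "W": 0.01, "Y": 0.04,
}

# Environment tilt scores. TM positions facing the lipids (facing coordinate
# +1) favor lipophilic types; buried/core-facing positions (-1) favor polar
# and charged ones. EM positions at the solvent-exposed loop apex (+1) favor
# charged types; positions packed near the bundle (-1) favor hydrophobics.
LIPO_SCORE = {
    "I": 1.0, "V": 1.0, "L": 1.0, "F": 1.0, "W": 1.0, "M": 1.0,
    "Y": 0.5, "A": 0.5, "G": 0.0, "S": 0.0, "T": 0.0, "P": 0.0, "C": 0.0,
    "N": -0.5, "Q": -0.5, "H": -0.5, "K": -1.0, "R": -1.0, "D": -1.0, "E": -1.0,
}
EXPO_SCORE = {
    "K": 1.0, "R": 1.0, "D": 1.0, "E": 1.0,
    "N": 0.5, "Q": 0.5, "S": 0.5, "T": 0.5, "H": 0.5,
    "G": 0.0, "P": 0.0, "A": -0.5, "C": -0.5, "Y": -0.5,
    "I": -1.0, "V": -1.0, "L": -1.0, "F": -1.0, "W": -1.0, "M": -1.0,
}

HELIX_RISE = 1.5          # Å per residue along the helix axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_CA_RADIUS = 2.3     # Å, CA distance from the helix axis
SIDECHAIN_EXTENT = 1.4    # Å, side-chain center beyond CA, radially
AXIS_SEPARATION = 10.4    # Å between adjacent helix axes in a bundle
STRAND_RISE = 3.3         # Å per residue along a beta strand
BARREL_RADIUS = 8.0       # Å, CA cylinder radius of the synthetic barrel
LOOP_SPACING = 3.4        # Å, target CA spacing along loops


@dataclass(frozen=True)
class PlantedContact:
    """A distance-specific group-group contact enriched in one region."""

    group1: str
    group2: str
    region: str = TM
    distance: float = 4.0
    excess: float = 0.3      # probability of retyping a candidate pair
    window: float = 0.3      # candidate pairs lie within distance +/- window
    max_per_protein: int = 4  # specific interactions are rare: cap per protein

    def __post_init__(self) -> None:
        if not (3.0 <= self.distance < 9.9):
            raise ValueError("target distance must lie within [3.0, 9.9) Å")
        if not (0.0 <= self.excess <= 1.0):
            raise ValueError("excess probability must be in [0, 1]")
        for g in (self.group1, self.group2):
            if g not in GROUP_MEMBERS:
                raise ValueError(f"unknown amino-acid group {g!r}")


@dataclass(frozen=True)
class FixtureConfig:
    n_proteins: int = 50
    alpha_fraction: float = 1.0  # remaining proteins are beta barrels
    n_tm_segments: int = 4
    tm_length: int = 28
    em_length: int = 16
    comp_tm: tuple[tuple[str, float], ...] = tuple(sorted(TM_COMPOSITION.items()))
    comp_em: tuple[tuple[str, float], ...] = tuple(sorted(EM_COMPOSITION.items()))
    planted: tuple[PlantedContact, ...] = ()
    sigma: float = 0.15  # Å of isotropic noise on side-chain centers
    uniform_geometry: bool = False  # null mode: all segments helical, one bundle
    # strength of the environment tilt on residue types: lipid-facing TM
    # positions favor aliphatic/aromatic types, buried TM positions polar and
    # charged ones, and solvent-exposed loop apices favor charged types, as
    # in real membrane proteins. 0 disables the tilt.
    facing_modulation: float = 2.0
    # veto types whose side chain cannot fit the local packing (see
    # generate_structure); disable to sample compositions exactly
    steric_budget: bool = True

    def __post_init__(self) -> None:
        for comp in (self.comp_tm, self.comp_em):
            keys = [k for k, _ in comp]
            if sorted(keys) != sorted(AA_ORDER):
                raise ValueError("composition tables must cover the 20 amino acids")
            total = sum(p for _, p in comp)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition must sum to 1, got {total}")

    @property
    def separable(self) -> bool:
        return bool(self.planted) or dict(self.comp_tm) != dict(self.comp_em)


def default_config(n_proteins: int = 50, **kw) -> FixtureConfig:
    """The separable study conditions: composition contrast plus planted
    region-specific contacts (TM salt bridges and packing contacts, EM polar
    and sulfur-aromatic contacts)."""
    planted = (
        PlantedContact("positive", "negative", TM, 4.0, 0.6, 0.35, 8),
        PlantedContact("positive", "aromatic", TM, 4.4, 0.6, 0.35, 8),
        PlantedContact("aliphatic", "aliphatic", TM, 4.6, 0.6, 0.35, 8),
        PlantedContact("aromatic", "aromatic", TM, 5.5, 0.6, 0.35, 8),
        PlantedContact("polar", "polar", EM, 4.5, 0.6, 0.35, 8),
        PlantedContact("sulfur", "aromatic", EM, 5.2, 0.6, 0.35, 8),
        PlantedContact("positive", "negative", EM, 5.0, 0.6, 0.35, 8),
    )
    return FixtureConfig(n_proteins=n_proteins, planted=planted, **kw)


def null_config(n_proteins: int = 40, **kw) -> FixtureConfig:
    """Matched null: identical TM/EM composition, no planted contacts, and a
    uniform helical-bundle geometry so the two regions are statistically
    indistinguishable by construction."""
    blend = {
        a: 0.5 * (TM_COMPOSITION[a] + EM_COMPOSITION[a]) for a in AA_ORDER
    }
    comp = tuple(sorted(blend.items()))
    return FixtureConfig(
        n_proteins=n_proteins,
        comp_tm=comp,
        comp_em=comp,
        planted=(),
        uniform_geometry=True,
        **kw,
    )


def _bundle_axes(n_helices: int) -> np.ndarray:
    if n_helices == 1:
        return np.zeros((1, 2))
    r = AXIS_SEPARATION / (2.0 * math.sin(math.pi / n_helices))
    angles = 2.0 * math.pi * np.arange(n_helices) / n_helices
    return np.column_stack([r * np.cos(angles), r * np.sin(angles)])


def _helix_positions(
    axis_xy: np.ndarray, length: int, up: bool, phase: float
) -> tuple[np.ndarray, np.ndarray]:
    """CA positions and radial unit vectors for one ideal helix."""
    i = np.arange(length, dtype=float)
    z = (i - (length - 1) / 2.0) * HELIX_RISE
    if not up:
        z = -z
    phi = phase + np.deg2rad(HELIX_TWIST) * i
    radial = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(length)])
    ca = np.column_stack(
        [axis_xy[0] + HELIX_CA_RADIUS * np.cos(phi),
         axis_xy[1] + HELIX_CA_RADIUS * np.sin(phi),
         z]
    )
    return ca, radial


def _loop_positions(p_from: np.ndarray, p_to: np.ndarray, n: int,
                    z_sign: float, rng: np.random.Generator) -> np.ndarray:
    """Arc of n CA positions bridging two attachment points outside the slab."""
    t = np.linspace(0.0, 1.0, n + 2)[1:-1]
    base = np.outer(1 - t, p_from) + np.outer(t, p_to)
    # bulge away from the membrane and outward so the arc is not compressed
    straight = np.linalg.norm(p_to - p_from)
    wanted = LOOP_SPACING * (n + 1)
    bulge = max(2.0, math.sqrt(max(wanted**2 - straight**2, 0.0)) / math.pi)
    out_xy = (p_from[:2] + p_to[:2]) / 2.0
    norm = np.linalg.norm(out_xy)
    out_dir = out_xy / norm if norm > 1e-9 else np.array([1.0, 0.0])
    base[:, 2] += z_sign * bulge * np.sin(np.pi * t)
    base[:, :2] += 0.35 * bulge * np.outer(np.sin(np.pi * t), out_dir)
    return base


def _tail_positions(p_from: np.ndarray, n: int, z_sign: float) -> np.ndarray:
    direction = np.array([0.45, 0.2, 0.0])
    xy = p_from[:2]
    norm = np.linalg.norm(xy)
    if norm > 1e-9:
        direction[:2] = xy / norm * 0.5
    direction[2] = z_sign * 0.85
    direction /= np.linalg.norm(direction)
    steps = np.arange(1, n + 1, dtype=float)[:, None]
    return p_from[None, :] + LOOP_SPACING * steps * direction


def _facing(dirs: np.ndarray, axis_xy: np.ndarray, center: np.ndarray) -> np.ndarray:
    """TM environment coordinate: +1 facing the lipids, -1 facing the core."""
    out = axis_xy - center
    nrm = np.linalg.norm(out)
    if nrm < 1e-9:
        return np.ones(len(dirs))
    out = out / nrm
    return dirs[:, :2] @ out


def _apexness(points: np.ndarray, z_top: float) -> np.ndarray:
    """EM environment coordinate: -1 near the membrane, +1 at the loop apex."""
    u = np.clip((np.abs(points[:, 2]) - z_top) / 6.0, 0.0, 1.0)
    return 2.0 * u - 1.0


def _alpha_geometry(config: FixtureConfig, rng: np.random.Generator):
    """CA positions, side-chain directions, region labels and environment
    coordinates for an alpha-helical bundle with EM tails and loops (or the
    uniform null bundle)."""
    z_top = config.tm_length * HELIX_RISE / 2.0
    if config.uniform_geometry:
        n_seg = 2 * config.n_tm_segments
        axes = _bundle_axes(n_seg)
        center = axes.mean(axis=0)
        cas, dirs, regions, env = [], [], [], []
        # which parity carries the TM label alternates randomly per protein,
        # so no label-correlated parity effect survives dataset pooling
        tm_parity = int(rng.integers(2))
        for k in range(n_seg):
            phase = rng.uniform(0.0, 2.0 * math.pi)
            ca, rad = _helix_positions(axes[k], config.tm_length, up=(k % 2 == 0),
                                       phase=phase)
            cas.append(ca)
            dirs.append(rad)
            regions.extend(
                [TM if k % 2 == tm_parity else EM] * config.tm_length
            )
            env.append(_facing(rad, axes[k], center))
        return np.vstack(cas), np.vstack(dirs), regions, np.concatenate(env)

    n_seg = config.n_tm_segments
    axes = _bundle_axes(n_seg)
    center = axes.mean(axis=0)
    helices = []
    for k in range(n_seg):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        ca, rad = _helix_positions(axes[k], config.tm_length, up=(k % 2 == 0),
                                   phase=phase)
        helices.append((ca, rad))

    cas, dirs, regions, env = [], [], [], []

    def radial_dirs(points: np.ndarray) -> np.ndarray:
        v = points[:, :2] - center[None, :]
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        nrm[nrm < 1e-9] = 1.0
        v = v / nrm
        return np.column_stack([v, np.zeros(len(points))])

    # N-terminal tail enters from the side where helix 0 starts (bottom)
    tail_n = _tail_positions(helices[0][0][0], config.em_length, z_sign=-1.0)[::-1]
    cas.append(tail_n)
    dirs.append(radial_dirs(tail_n))
    regions.extend([EM] * config.em_length)
    env.append(_apexness(tail_n, z_top))

    for k, (ca, rad) in enumerate(helices):
        cas.append(ca)
        dirs.append(rad)
        regions.extend([TM] * config.tm_length)
        env.append(_facing(rad, axes[k], center))
        if k + 1 < n_seg:
            nxt = helices[k + 1][0]
            z_sign = 1.0 if ca[-1][2] > 0 else -1.0
            loop = _loop_positions(ca[-1], nxt[0], config.em_length, z_sign, rng)
            cas.append(loop)
            dirs.append(radial_dirs(loop))
            regions.extend([EM] * config.em_length)
            env.append(_apexness(loop, z_top))

    last_ca = helices[-1][0][-1]
    tail_c = _tail_positions(last_ca, config.em_length,
                             z_sign=1.0 if last_ca[2] > 0 else -1.0)
    cas.append(tail_c)
    dirs.append(radial_dirs(tail_c))
    regions.extend([EM] * config.em_length)
    env.append(_apexness(tail_c, z_top))
    return np.vstack(cas), np.vstack(dirs), regions, np.concatenate(env)


def _barrel_geometry(config: FixtureConfig, rng: np.random.Generator):
    """CA positions, side-chain directions, labels and environment
    coordinates for a beta barrel."""
    n_strands = max(2 * config.n_tm_segments, 8)
    length = max(config.tm_length // 2 + 2, 10)
    z_top = length * STRAND_RISE / 2.0
    angles = 2.0 * math.pi * np.arange(n_strands) / n_strands
    cas, dirs, regions, env = [], [], [], []
    prev_end = None
    for k in range(n_strands):
        i = np.arange(length, dtype=float)
        z = (i - (length - 1) / 2.0) * STRAND_RISE
        if k % 2 == 1:
            z = -z
        theta = angles[k] + 0.035 * (i - (length - 1) / 2.0)
        ca = np.column_stack(
            [BARREL_RADIUS * np.cos(theta), BARREL_RADIUS * np.sin(theta), z]
        )
        # side chains alternate pointing into the lumen and out to the lipids
        sign = np.where(i.astype(int) % 2 == 0, -1.0, 1.0)
        rad = np.column_stack(
            [sign * np.cos(theta), sign * np.sin(theta), np.zeros(length)]
        )
        if prev_end is not None:
            z_sign = 1.0 if prev_end[2] > 0 else -1.0
            loop = _loop_positions(prev_end, ca[0], config.em_length, z_sign, rng)
            v = loop[:, :2]
            nrm = np.linalg.norm(v, axis=1, keepdims=True)
            nrm[nrm < 1e-9] = 1.0
            cas.append(loop)
            dirs.append(np.column_stack([v / nrm, np.zeros(len(loop))]))
            regions.extend([EM] * config.em_length)
            env.append(_apexness(loop, z_top))
        cas.append(ca)
        dirs.append(rad)
        regions.extend([TM] * length)
        env.append(sign)  # outward-facing strand positions see the lipids
        prev_end = ca[-1]
    return np.vstack(cas), np.vstack(dirs), regions, np.concatenate(env)


def _plant_types(
    aas: np.ndarray,
    centers: np.ndarray,
    regions: list[str],
    planted: tuple[PlantedContact, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-resample residue types at spatially close position pairs.

    The planted distance is a contact (surface) distance: the member types
    chosen for a candidate pair are those whose radius shifts make the
    geometric center distance consistent with ``target + shift(s1) +
    shift(s2)``, as in real interactions where bigger side chains touch at
    larger center separations. Pooled group counts, which subtract exactly
    those shifts, therefore concentrate at the target distance.

    Planted interactions are specific and rare: at most ``max_per_protein``
    pairs per contact type are planted, candidates are visited in random
    order, and residues already planted are never retyped by a later
    contact, so contact types do not silently overwrite each other.
    """
    if not planted:
        return aas, []
    from .contact_counts import GROUPS
    from .structure_io import default_radius_table

    radii = default_radius_table()
    regions_arr = np.array(regions)
    seq = np.arange(1, len(aas) + 1)
    ii, jj = np.triu_indices(len(aas), k=1)
    eligible = np.abs(seq[ii] - seq[jj]) > 1
    ii, jj = ii[eligible], jj[eligible]
    d = np.linalg.norm(centers[ii] - centers[jj], axis=1)
    locked = np.zeros(len(aas), dtype=bool)
    n_candidates = []
    for pc in planted:
        sh1 = GROUPS[pc.group1].shifts(radii)
        sh2 = GROUPS[pc.group2].shifts(radii)
        combos = [
            (s1, s2, sh1[s1] + sh2[s2])
            for s1 in GROUP_MEMBERS[pc.group1]
            for s2 in GROUP_MEMBERS[pc.group2]
        ]
        max_shift = max(c[2] for c in combos)
        in_region = (regions_arr[ii] == pc.region) & (regions_arr[jj] == pc.region)
        near = (d >= pc.distance - pc.window) & (d <= pc.distance + pc.window + max_shift)
        cand = rng.permutation(np.nonzero(in_region & near)[0])
        n_candidates.append(int(len(cand)))
        n_planted = 0
        for k in cand:
            if n_planted >= pc.max_per_protein:
                break
            if locked[ii[k]] or locked[jj[k]]:
                continue
            if rng.random() >= pc.excess:
                continue
            # triangular weight in the shift-corrected distance per combo
            weights = np.array(
                [max(0.0, 1.0 - abs(d[k] - (pc.distance + dsum)) / pc.window)
                 for _, _, dsum in combos]
            )
            if weights.sum() <= 0:
                continue
            pick = rng.choice(len(combos), p=weights / weights.sum())
            s1, s2, _ = combos[pick]
            a, b = (ii[k], jj[k]) if rng.random() < 0.5 else (jj[k], ii[k])
            aas[a], aas[b] = s1, s2
            locked[a] = locked[b] = True
            n_planted += 1
    return aas, n_candidates


def generate_structure(
    config: FixtureConfig,
    seed: int,
    structure_id: str = "SYN0001",
    topology: str = "alpha_helical",
) -> tuple[str, list[Segment], dict]:
    """One synthetic protein: PDB text, region segments, truth metadata."""
    rng = np.random.default_rng([int(seed), 0xA11CE])
    if topology == "beta_barrel" and not config.uniform_geometry:
        cas, radial, regions, env = _barrel_geometry(config, rng)
    else:
        cas, radial, regions, env = _alpha_geometry(config, rng)
    centers = cas + SIDECHAIN_EXTENT * radial
    centers = centers + rng.normal(scale=config.sigma, size=centers.shape)

    comp_tm = np.array([dict(config.comp_tm)[a] for a in AA_ORDER])
    comp_em = np.array([dict(config.comp_em)[a] for a in AA_ORDER])
    lipo = np.array([LIPO_SCORE[a] for a in AA_ORDER])
    expo = np.array([EXPO_SCORE[a] for a in AA_ORDER])
    eta = config.facing_modulation

    # Steric budget: a side chain must fit the space around its position.
    # Using the nearest non-adjacent neighbor distance dmin, admit only types
    # whose radius is at most (dmin - 0.8)/2, so that two admitted neighbors
    # keep their surfaces ~0.8 Å apart. Real structures never show bulky
    # pairs at overlapping center distances; without this veto the shifted
    # group counts acquire impossible short-distance mass.
    from .structure_io import default_radius_table

    radius_vec = np.array([default_radius_table()[a] for a in AA_ORDER])
    n_res = len(centers)
    seq = np.arange(n_res)
    diff = centers[:, None, :] - centers[None, :, :]
    dmat = np.sqrt((diff ** 2).sum(axis=2))
    adjacent = np.abs(seq[:, None] - seq[None, :]) <= 1
    dmat[adjacent] = np.inf
    dmin = dmat.min(axis=1)
    if config.steric_budget:
        budget = (dmin - 0.8) / 2.0
    else:
        budget = np.full(n_res, np.inf)

    alphabet = list(AA_ORDER)
    aa_list = []
    for reg, u, b in zip(regions, env, budget):
        base = comp_tm if reg == TM else comp_em
        if config.uniform_geometry:
            # matched null: one tilt for both labels, or the tilt itself
            # would couple types to contacts differently per region
            score = lipo
        else:
            score = lipo if reg == TM else expo
        p = base * np.exp(eta * score * u)
        p = np.where(radius_vec <= b, p, 0.0)
        if p.sum() <= 0:
            p = np.where(radius_vec <= radius_vec.min() + 1e-9, 1.0, 0.0)
        aa_list.append(rng.choice(alphabet, p=p / p.sum()))
    aas = np.array(aa_list)
    aas, planted_candidates = _plant_types(aas, centers, regions, config.planted, rng)
    # Gly has no side chain: its interaction center is CA by convention
    centers[aas == "G"] = cas[aas == "G"]

    lines = []
    serial = 1
    for n, (aa, ca, ctr) in enumerate(zip(aas, cas, centers), start=1):
        from .aa import ONE_TO_THREE

        res3 = ONE_TO_THREE[aa]
        records = [("N", ca + np.array([-0.5, 0.4, -0.9]), "N"),
                   ("CA", ca, "C"),
                   ("C", ca + np.array([0.6, -0.4, 0.8]), "C")]
        if aa != "G":
            records.append(("CB", ctr, "C"))
        for name, xyz, element in records:
            lines.append(
                f"ATOM  {serial:>5} {name:<4} {res3:>3} A{n:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2}"
            )
            serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    segments = []
    start = 0
    for k in range(1, len(regions) + 1):
        if k == len(regions) or regions[k] != regions[start]:
            segments.append(
                Segment(structure_id, "A", start + 1, k, regions[start])
            )
            start = k
    truth = {
        "structure_id": structure_id,
        "topology": topology if not config.uniform_geometry else "alpha_helical",
        "n_residues": int(len(aas)),
        "n_tm": int(sum(r == TM for r in regions)),
        "n_em": int(sum(r == EM for r in regions)),
        "planted_candidates": planted_candidates,
        "seed": int(seed),
    }
    return pdb_text, segments, truth


@dataclass
class SyntheticDataset:
    structures: list[LabeledStructure]
    annotation: RegionAnnotation
    truth: dict
    pdb_texts: dict[str, str] = field(default_factory=dict)


def generate_dataset(
    config: FixtureConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """A full dataset of parsed, region-labeled synthetic structures.

    Every structure goes through PDB text and the regular parser, so the
    fixtures exercise the same input path as real data. With ``outdir`` the
    PDB files, the annotation TSV and a truth JSON are also written.
    """
    structures = []
    pdb_texts = {}
    all_segments = []
    truths = []
    n_alpha = int(round(config.alpha_fraction * config.n_proteins))
    for k in range(config.n_proteins):
        sid = f"SYN{k:04d}"
        topology = "alpha_helical" if k < n_alpha else "beta_barrel"
        pdb_text, segments, truth = generate_structure(
            config, seed=int(seed) * 100003 + k, structure_id=sid, topology=topology
        )
        st = parse_structure(pdb_text, sid, topology_class=truth["topology"])
        st = assign_regions(st, RegionAnnotation(segments))
        structures.append(st)
        pdb_texts[sid] = pdb_text
        all_segments.extend(segments)
        truths.append(truth)
    annotation = RegionAnnotation(all_segments)
    if config.planted:
        totals = np.sum([t["planted_candidates"] for t in truths], axis=0)
        for pc, total in zip(config.planted, totals):
            if total == 0:
                raise ValueError(
                    f"infeasible geometry: no candidate pairs anywhere in the "
                    f"dataset for planted contact {pc.group1}-{pc.group2} at "
                    f"{pc.distance} Å in {pc.region}"
                )
    truth = {
        "separable": config.separable,
        "n_proteins": config.n_proteins,
        "planted": [asdict(p) for p in config.planted],
        "comp_tm": dict(config.comp_tm),
        "comp_em": dict(config.comp_em),
        "uniform_geometry": config.uniform_geometry,
        "seed": int(seed),
        "proteins": truths,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, text in pdb_texts.items():
            (outdir / f"{sid}.pdb").write_text(text)
        (outdir / "annotation.tsv").write_text(annotation.to_tsv())
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return SyntheticDataset(structures, annotation, truth, pdb_texts)


def region_composition(structures: list[LabeledStructure]):
    """Relative amino-acid frequencies per region (columns sum to 1)."""
    import pandas as pd

    counts: dict[str, dict[str, int]] = {}
    for st in structures:
        for r in st.residues:
            counts.setdefault(r.region, {a: 0 for a in AA_ORDER})
            counts[r.region][r.aa] += 1
    if not counts:
        raise ValueError("no residues")
    table = pd.DataFrame(counts).reindex(list(AA_ORDER)).fillna(0)
    totals = table.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a region has no residues")
    return table / totals
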