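"""Binned occurrence counts of residue types and pairs vs. center distance.

Distances between side-chain geometric centers of residues separated by more
than one position along the chain are histogrammed into 0.3 Å bins over
[3.0, 9.9) Å plus one overflow bin for everything beyond. Counts are kept per
region (TM / EM, or GL for whole globular structures), with per-protein
sub-counts for exact leave-one-out subtraction, and can be smoothed with a
truncated geometric kernel to tame sparse-data noise.

Storage conventions (asserted in tests):

* pair tables use symmetric double storage — each pair event (s1, s2, bin)
  increments both ``pair[s1, s2, bin]`` and ``pair[s2, s1, bin]`` (the
  diagonal twice), so ``pair.sum() == 2 * n_events``;
* single tables count each endpoint of each event once, so
  ``single.sum() == 2 * n_events`` and both tables share the same distance
  marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .aa import AA_INDEX, AA_ORDER, GROUP_MEMBERS, N_AA
from .structure_io import EM, TM, UNASSIGNED, LabeledStructure, RadiusTable

GL = "GL"
REGIONS = (TM, EM, GL)

SMOOTH_BETA = 4          # neighborhood half-width, in bins
SMOOTH_ALPHA = 4.0 / 3.0  # geometric decay base; weight (1/alpha)^i = (3/4)^i


@dataclass(frozen=True)
class BinningScheme:
    """0.3 Å bins from 3.0 Å; 23 regular bins + 1 overflow for d >= 9.9 Å."""

    lower: float = 3.0
    width: float = 0.3
    n_regular: int = 23
    sub3_policy: str = "clamp_to_first"  # or "discard"

    def __post_init__(self) -> None:
        if self.sub3_policy not in ("clamp_to_first", "discard"):
            raise ValueError(f"unknown sub-3 Å policy {self.sub3_policy!r}")

    @property
    def n_bins(self) -> int:
        return self.n_regular + 1

    @property
    def overflow_bin(self) -> int:
        return self.n_regular

    @property
    def upper(self) -> float:
        return self.lower + self.width * self.n_regular

    def lower_edge(self, b: int) -> float:
        return self.lower + self.width * b

    def bin_array(self, d: np.ndarray) -> np.ndarray:
        """Vectorized binning; -1 marks discarded sub-3 Å distances."""
        d = np.asarray(d, dtype=float)
        if np.any(~np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")
        # epsilon guards the exact bin edges against float round-off
        # (3.3 - 3.0 is slightly below 0.3 in binary)
        b = np.floor((d - self.lower) / self.width + 1e-9).astype(int)
        b = np.minimum(b, self.overflow_bin)
        if self.sub3_policy == "clamp_to_first":
            b = np.maximum(b, 0)
        else:
            b[b < 0] = -1
        return b


DEFAULT_SCHEME = BinningScheme()


def distance_to_bin(d: float, scheme: BinningScheme = DEFAULT_SCHEME) -> int | None:
    """Bin index for one distance; None if discarded by the sub-3 Å policy."""
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"distance must be finite and non-negative, got {d!r}")
    b = int(scheme.bin_array(np.array([d]))[0])
    return None if b < 0 else b


def smoothing_kernel(scheme: BinningScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Bin-to-bin smoothing matrix K: smoothed = counts @ K.

    Regular bins receive (3/4)^|offset| from neighbors up to 4 bins away,
    truncated at the boundaries; the overflow bin is excluded both as source
    and recipient (it aggregates an unbounded distance range).
    """
    n = scheme.n_bins
    k = np.zeros((n, n))
    for i in range(scheme.n_regular):
        for j in range(scheme.n_regular):
            off = abs(i - j)
            if off <= SMOOTH_BETA:
                k[i, j] = (1.0 / SMOOTH_ALPHA) ** off
    k[scheme.overflow_bin, scheme.overflow_bin] = 1.0
    return k


@dataclass(frozen=True)
class GroupDef:
    """A physicochemical amino-acid group for pooled potentials."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        for m in self.members:
            if m not in AA_ORDER:
                raise ValueError(f"unknown amino acid {m!r} in group {self.name}")

    def shifts(self, radii: RadiusTable) -> dict[str, float]:
        """Distance shift per member: radius minus the group's smallest radius."""
        base = min(radii[m] for m in self.members)
        return {m: radii[m] - base for m in self.members}


GROUPS = {name: GroupDef(name, members) for name, members in GROUP_MEMBERS.items()}


@dataclass
class PairCounts:
    """Binned single-type and pair counts for one region dataset."""

    region: str
    scheme: BinningScheme
    pair: np.ndarray    # (20, 20, n_bins), symmetric double storage
    single: np.ndarray  # (20, n_bins)
    smoothed: bool = False
    per_protein: dict[str, "PairCounts"] | None = None
    inter_chain: bool = False

    @classmethod
    def zeros(cls, region: str, scheme: BinningScheme = DEFAULT_SCHEME,
              inter_chain: bool = False) -> "PairCounts":
        return cls(
            region=region,
            scheme=scheme,
            pair=np.zeros((N_AA, N_AA, scheme.n_bins)),
            single=np.zeros((N_AA, scheme.n_bins)),
            inter_chain=inter_chain,
        )

    # --- marginals (recomputed from the tables, so they remain consistent
    # after smoothing by construction) -------------------------------------
    @property
    def pair_aa(self) -> np.ndarray:
        return self.pair.sum(axis=2)

    @property
    def single_aa(self) -> np.ndarray:
        return self.single.sum(axis=1)

    @property
    def dist(self) -> np.ndarray:
        return self.pair.sum(axis=(0, 1))

    @property
    def dist_single(self) -> np.ndarray:
        return self.single.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.pair.sum())

    @property
    def total_single(self) -> float:
        return float(self.single.sum())

    @property
    def n_events(self) -> float:
        return self.total / 2.0

    # --- arithmetic for pooling and LOO subtraction ------------------------
    def _compatible(self, other: "PairCounts") -> None:
        if self.region != other.region or self.scheme != other.scheme:
            raise ValueError("cannot combine counts with different region/scheme")
        if self.smoothed or other.smoothed:
            raise ValueError("pooling/subtraction operates on raw counts only")

    def __add__(self, other: "PairCounts") -> "PairCounts":
        self._compatible(other)
        return PairCounts(self.region, self.scheme, self.pair + other.pair,
                          self.single + other.single, inter_chain=self.inter_chain)

    def subtract(self, other: "PairCounts") -> "PairCounts":
        self._compatible(other)
        pair = self.pair - other.pair
        single = self.single - other.single
        if pair.min() < 0 or single.min() < 0:
            raise ValueError("subtraction produced negative counts")
        return PairCounts(self.region, self.scheme, pair, single,
                          inter_chain=self.inter_chain)

    # --- serialization -----------------------------------------------------
    def to_tsv(self) -> str:
        rows = ["region\taa1\taa2\tbin_lower_edge\tcount"]
        for s1 in range(N_AA):
            for b in range(self.scheme.n_bins):
                c = self.single[s1, b]
                if c:
                    rows.append(f"{self.region}\t{AA_ORDER[s1]}\t.\t"
                                f"{self.scheme.lower_edge(b):.1f}\t{float(c)!r}")
            for s2 in range(N_AA):
                for b in range(self.scheme.n_bins):
                    c = self.pair[s1, s2, b]
                    if c:
                        rows.append(f"{self.region}\t{AA_ORDER[s1]}\t{AA_ORDER[s2]}\t"
                                    f"{self.scheme.lower_edge(b):.1f}\t{float(c)!r}")
        return "\n".join(rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str, scheme: BinningScheme = DEFAULT_SCHEME) -> "PairCounts":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        region = None
        out = None
        for ln in lines[1:]:
            reg, a1, a2, edge, count = ln.split("\t")
            if out is None:
                region = reg
                out = cls.zeros(region, scheme)
            b = int(round((float(edge) - scheme.lower) / scheme.width))
            if a2 == ".":
                out.single[AA_INDEX[a1], b] = float(count)
            else:
                out.pair[AA_INDEX[a1], AA_INDEX[a2], b] = float(count)
        if out is None:
            raise ValueError("empty counts table")
        return out


def _structure_pairs(
    st: LabeledStructure, scheme: BinningScheme, inter_chain: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All chain-eligible residue pairs: (i, j, aa index arrays, bin array).

    Same-chain pairs need |seq_index difference| > 1; inter-chain pairs (when
    enabled) are always eligible. Discarded sub-3 Å pairs are removed.
    """
    n = len(st.residues)
    centers = np.array([r.center for r in st.residues])
    chains = np.array([r.chain_id for r in st.residues])
    seq = np.array([r.seq_index for r in st.residues])
    ii, jj = np.triu_indices(n, k=1)
    same_chain = chains[ii] == chains[jj]
    eligible = same_chain & (np.abs(seq[ii] - seq[jj]) > 1)
    if inter_chain:
        eligible |= ~same_chain
    ii, jj = ii[eligible], jj[eligible]
    d = np.linalg.norm(centers[ii] - centers[jj], axis=1)
    bins = scheme.bin_array(d)
    keep = bins >= 0
    return ii[keep], jj[keep], d[keep], bins[keep]


def _count_structure(
    st: LabeledStructure, region: str, scheme: BinningScheme, inter_chain: bool
) -> PairCounts:
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}, got {region!r}")
    if region != GL and any(r.region == UNASSIGNED for r in st.residues):
        raise ValueError(
            f"{st.structure_id}: residues have UNASSIGNED regions; "
            "run assign_regions first"
        )
    out = PairCounts.zeros(region, scheme, inter_chain=inter_chain)
    ii, jj, _, bins = _structure_pairs(st, scheme, inter_chain)
    aas = np.array([AA_INDEX[r.aa] for r in st.residues])
    if region != GL:
        regs = np.array([r.region for r in st.residues])
        both = (regs[ii] == region) & (regs[jj] == region)
        ii, jj, bins = ii[both], jj[both], bins[both]
    s1, s2 = aas[ii], aas[jj]
    np.add.at(out.pair, (s1, s2, bins), 1.0)
    np.add.at(out.pair, (s2, s1, bins), 1.0)
    np.add.at(out.single, (s1, bins), 1.0)
    np.add.at(out.single, (s2, bins), 1.0)
    return out


def accumulate_pair_counts(
    structures: list[LabeledStructure],
    region: str,
    scheme: BinningScheme = DEFAULT_SCHEME,
    inter_chain: bool = False,
) -> PairCounts:
    """Pool binned pair/single counts over structures for one region dataset.

    Both endpoints of a pair must carry the requested region label
    (cross-boundary pairs are discarded); ``region="GL"`` counts all residues
    of each structure, for the globular-protein reference dataset.
    Per-protein sub-counts are retained for leave-one-out subtraction.
    """
    if not structures:
        raise ValueError("no structures to count")
    per_protein = {}
    pooled = PairCounts.zeros(region, scheme, inter_chain=inter_chain)
    for st in structures:
        if st.structure_id in per_protein:
            raise ValueError(f"duplicate structure_id {st.structure_id!r}")
        sub = _count_structure(st, region, scheme, inter_chain)
        per_protein[st.structure_id] = sub
        pooled = pooled + sub
    pooled.per_protein = per_protein
    return pooled


def smooth_counts(raw: "PairCounts | GroupCounts") -> "PairCounts | GroupCounts":
    """Spread each regular bin's occurrences over its 4-bin neighborhood with
    geometric weights (3/4)^offset; the overflow bin is left untouched."""
    if raw.smoothed:
        raise ValueError("counts are already smoothed")
    k = smoothing_kernel(raw.scheme)
    if isinstance(raw, GroupCounts):
        return replace(raw, counts=raw.counts @ k, ref_dist=raw.ref_dist @ k,
                       smoothed=True)
    return PairCounts(
        region=raw.region,
        scheme=raw.scheme,
        pair=raw.pair @ k,
        single=raw.single @ k,
        smoothed=True,
        inter_chain=raw.inter_chain,
    )


@dataclass
class GroupCounts:
    """Pooled, radius-shifted pair counts for one group pair.

    ``counts`` holds one increment per eligible pair event (triangular, 1x
    storage); ``ref_dist`` is the distance marginal of the full unshifted pair
    table of the same dataset, which supplies the n(d) and n reference terms.
    """

    region: str
    scheme: BinningScheme
    group1: GroupDef
    group2: GroupDef
    counts: np.ndarray    # (n_bins,)
    ref_dist: np.ndarray  # (n_bins,)
    smoothed: bool = False
    inter_chain: bool = False

    @property
    def group_total(self) -> float:
        return float(self.counts.sum())

    @property
    def ref_total(self) -> float:
        return float(self.ref_dist.sum())


def pool_group_counts(
    structures: list[LabeledStructure],
    region: str,
    groups: tuple[GroupDef, GroupDef],
    radii: RadiusTable,
    scheme: BinningScheme = DEFAULT_SCHEME,
    inter_chain: bool = False,
) -> GroupCounts:
    """Pool pair counts over a group pair with radius-difference shifts.

    For each eligible pair with one residue in each group, the continuous
    distance is reduced by both members' shifts (radius minus the smallest
    radius in the respective group) before binning; shifted distances below
    3 Å follow the scheme's sub-3 Å policy.
    """
    if not structures:
        raise ValueError("no structures to count")
    g1, g2 = groups
    set1, set2 = set(g1.members), set(g2.members)
    if set1 != set2 and set1 & set2:
        raise ValueError("group members must be disjoint or identical")
    shift1, shift2 = g1.shifts(radii), g2.shifts(radii)

    counts = np.zeros(scheme.n_bins)
    ref_dist = np.zeros(scheme.n_bins)
    for st in structures:
        if region != GL and any(r.region == UNASSIGNED for r in st.residues):
            raise ValueError(f"{st.structure_id}: residues have UNASSIGNED regions")
        ii, jj, d, bins = _structure_pairs(st, scheme, inter_chain)
        aas = np.array([r.aa for r in st.residues])
        if region != GL:
            regs = np.array([r.region for r in st.residues])
            both = (regs[ii] == region) & (regs[jj] == region)
            ii, jj, d, bins = ii[both], jj[both], d[both], bins[both]
        np.add.at(ref_dist, bins, 1.0)
        a_i, a_j = aas[ii], aas[jj]
        in12 = np.isin(a_i, list(set1)) & np.isin(a_j, list(set2))
        if set1 == set2:
            # identical groups: in12 already covers every unordered event once
            selections = [(in12, shift1, shift1)]
        else:
            in21 = np.isin(a_i, list(set2)) & np.isin(a_j, list(set1))
            selections = [(in12, shift1, shift2), (in21, shift2, shift1)]
        for sel, sh_i, sh_j in selections:
            idx = np.nonzero(sel)[0]
            if idx.size == 0:
                continue
            dd = d[idx] - np.array([sh_i[a] for a in a_i[idx]]) \
                        - np.array([sh_j[a] for a in a_j[idx]])
            if scheme.sub3_policy == "discard":
                dd = dd[dd >= 0.0]
            else:
                dd = np.maximum(dd, 0.0)
            b = scheme.bin_array(dd)
            b = b[b >= 0]
            np.add.at(counts, b, 1.0)
    ref_dist *= 2.0  # match the double-storage distance marginal convention
    return GroupCounts(region, scheme, g1, g2, counts, ref_dist,
                       inter_chain=inter_chain)
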