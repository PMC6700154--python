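"""Inverse-Boltzmann distance potentials from binned counts.

The central quantity is the knowledge-based pair potential

    dW(s1, s2, d) = -kB*T * ln[ n(s1,s2,d) * n / (n(s1,s2) * n(d)) ]

and its single-type analogue dW(s, d), evaluated on smoothed counts with a
sparse-data guard: bins whose (smoothed, by default) occurrence count falls
below a threshold of 10 are set to zero and masked, as are bins with a zero
reference denominator. Group potentials apply the same formula to
radius-shifted, group-pooled counts against the full dataset's distance
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aa import AA_INDEX, AA_ORDER, N_AA
from .contact_counts import (
    DEFAULT_SCHEME,
    BinningScheme,
    GroupCounts,
    PairCounts,
    smooth_counts,
)

#: kB * 298.15 K in kcal/mol ("room temperature"); configurable everywhere.
KBT_ROOM = 0.5925

#: Minimum (smoothed) occurrence count for a bin to yield a potential value.
COUNT_THRESHOLD = 10.0

FLAVORS = ("sd", "sds", "group")


@dataclass
class PotentialTable:
    """dW values (kcal/mol) per amino acid / pair / group pair per bin.

    ``values`` has shape (20, n_bins) for flavor "sd", (20, 20, n_bins) for
    "sds", and (n_bins,) for "group". ``mask`` marks bins suppressed by the
    occurrence threshold or a zero denominator; masked values are exactly 0.
    """

    flavor: str
    region: str
    kbt: float
    values: np.ndarray
    mask: np.ndarray
    scheme: BinningScheme
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flavor not in FLAVORS:
            raise ValueError(f"flavor must be one of {FLAVORS}")
        if self.kbt <= 0:
            raise ValueError("kBT must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential values must be finite")
        if np.any(self.values[self.mask] != 0.0):
            raise ValueError("masked bins must be exactly 0")
        if self.flavor == "sds" and not np.allclose(
            self.values, self.values.swapaxes(0, 1)
        ):
            raise ValueError("sds potential must be symmetric in (s1, s2)")


def _guard_tables(counts, flavor):
    if flavor == "sd":
        return counts.single
    if flavor == "sds":
        return counts.pair
    return counts.counts


def derive_potential(
    counts: PairCounts,
    flavor: str,
    kbt: float = KBT_ROOM,
    threshold: float = COUNT_THRESHOLD,
    guard_counts: PairCounts | None = None,
    allow_unsmoothed: bool = False,
) -> PotentialTable:
    """Turn (smoothed) counts into dW(s,d) or dW(s1,s2,d).

    The sparse-data guard inspects the same smoothed counts by default; pass
    the raw table as ``guard_counts`` to evaluate the threshold on raw
    occurrences instead. Deriving from unsmoothed counts requires
    ``allow_unsmoothed=True``.
    """
    if flavor not in ("sd", "sds"):
        raise ValueError("derive_potential handles flavors 'sd' and 'sds'")
    if kbt <= 0:
        raise ValueError("kBT must be positive")
    if not counts.smoothed and not allow_unsmoothed:
        raise ValueError(
            "counts are not smoothed; smooth_counts first or pass allow_unsmoothed=True"
        )
    if flavor == "sd":
        tbl = counts.single
        marg_aa = counts.single_aa[:, None]
        dist = counts.dist_single[None, :]
        total = counts.total_single
    else:
        tbl = counts.pair
        marg_aa = counts.pair_aa[:, :, None]
        dist = counts.dist[None, None, :]
        total = counts.total
    guard = _guard_tables(guard_counts, flavor) if guard_counts is not None else tbl

    denom = marg_aa * dist
    ok = (guard >= threshold) & (denom > 0) & (tbl > 0) & (total > 0)
    values = np.zeros_like(tbl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, tbl * total / np.where(denom > 0, denom, 1.0), 1.0)
        values[ok] = -kbt * np.log(ratio[ok])
    return PotentialTable(
        flavor=flavor,
        region=counts.region,
        kbt=kbt,
        values=values,
        mask=~ok,
        scheme=counts.scheme,
        provenance={
            "threshold": threshold,
            "threshold_on": "raw" if guard_counts is not None else "smoothed",
            "inter_chain": counts.inter_chain,
        },
    )


def derive_group_potential(
    group_counts: GroupCounts,
    kbt: float = KBT_ROOM,
    threshold: float = COUNT_THRESHOLD,
    guard_counts: GroupCounts | None = None,
    allow_unsmoothed: bool = False,
) -> PotentialTable:
    """dW for a pooled group pair against the full-dataset distance reference."""
    if kbt <= 0:
        raise ValueError("kBT must be positive")
    if not group_counts.smoothed and not allow_unsmoothed:
        raise ValueError("group counts are not smoothed")
    c = group_counts.counts
    denom = group_counts.group_total * group_counts.ref_dist
    guard = guard_counts.counts if guard_counts is not None else c
    ok = (guard >= threshold) & (denom > 0) & (c > 0)
    values = np.zeros_like(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, c * group_counts.ref_total / np.where(denom > 0, denom, 1.0), 1.0)
        values[ok] = -kbt * np.log(ratio[ok])
    return PotentialTable(
        flavor="group",
        region=group_counts.region,
        kbt=kbt,
        values=values,
        mask=~ok,
        scheme=group_counts.scheme,
        provenance={
            "threshold": threshold,
            "group1": group_counts.group1.name,
            "group2": group_counts.group2.name,
            "inter_chain": group_counts.inter_chain,
        },
    )


def build_potential(
    raw_counts: PairCounts,
    flavor: str,
    kbt: float = KBT_ROOM,
    threshold: float = COUNT_THRESHOLD,
    threshold_on: str = "raw",
) -> PotentialTable:
    """Standard pipeline: guard on raw occurrences, smooth, derive.

    The sparse-data layers apply in that order — a bin is dropped when its
    *raw* occurrence count is below the threshold, and the surviving values
    are computed from smoothed counts. ``threshold_on="smoothed"`` instead
    evaluates the guard on the smoothed counts; near the 3 Å boundary that
    variant can leave almost-empty bins unmasked (their smoothed count is
    borrowed from neighbors while the reference n(d) stays tiny), producing
    spuriously deep boundary values.
    """
    smoothed = smooth_counts(raw_counts)
    guard = raw_counts if threshold_on == "raw" else None
    return derive_potential(smoothed, flavor, kbt, threshold, guard_counts=guard)


def build_group_potential(
    raw_group_counts: GroupCounts,
    kbt: float = KBT_ROOM,
    threshold: float = COUNT_THRESHOLD,
    threshold_on: str = "raw",
) -> PotentialTable:
    """Group-potential pipeline with the same layer order as build_potential."""
    smoothed = smooth_counts(raw_group_counts)
    guard = raw_group_counts if threshold_on == "raw" else None
    return derive_group_potential(smoothed, kbt, threshold, guard_counts=guard)


@dataclass
class PotentialDifference:
    """Per-bin difference a - b restricted to bins unmasked in both tables."""

    diff: np.ndarray
    comparable: np.ndarray  # bool mask of bins entering the comparison
    mean_shift: float
    min_value: float | None
    min_bin: int | None
    n_comparable: int


def potential_difference(a: PotentialTable, b: PotentialTable) -> PotentialDifference:
    """Compare two potentials of the same flavor and indexing."""
    if a.flavor != b.flavor or a.values.shape != b.values.shape:
        raise ValueError("potential tables have mismatched flavor or shape")
    comparable = ~(a.mask | b.mask)
    diff = np.where(comparable, a.values - b.values, 0.0)
    n = int(comparable.sum())
    if n == 0:
        return PotentialDifference(diff, comparable, float("nan"), None, None, 0)
    mean_shift = float(diff[comparable].mean())
    flat = np.where(comparable, diff, np.inf).reshape(-1)
    kmin = int(np.argmin(flat))
    return PotentialDifference(
        diff=diff,
        comparable=comparable,
        mean_shift=mean_shift,
        min_value=float(flat[kmin]),
        min_bin=kmin % a.values.shape[-1],
        n_comparable=n,
    )


def potential_minimum(table: PotentialTable) -> tuple[int | None, float | None]:
    """Location (bin) and depth of the deepest unmasked value; (None, None)
    if every bin is masked."""
    ok = ~table.mask
    if not ok.any():
        return None, None
    flat = np.where(ok, table.values, np.inf).reshape(-1)
    k = int(np.argmin(flat))
    return k % table.values.shape[-1], float(flat[k])


# --- TSV persistence -------------------------------------------------------

def potential_to_tsv(table: PotentialTable) -> str:
    """Serialize as TSV with repr-precision values (bit-exact round trip)."""
    rows = ["flavor\tregion\ts1\ts2\tbin_lower_edge_A\tdeltaW_kcal_mol\tmasked"]

    def emit(s1: str, s2: str, vec: np.ndarray, msk: np.ndarray) -> None:
        for b in range(table.scheme.n_bins):
            rows.append(
                f"{table.flavor}\t{table.region}\t{s1}\t{s2}\t"
                f"{table.scheme.lower_edge(b):.1f}\t{float(vec[b])!r}\t{int(msk[b])}"
            )

    if table.flavor == "sd":
        for i, a in enumerate(AA_ORDER):
            emit(a, "-", table.values[i], table.mask[i])
    elif table.flavor == "sds":
        for i, a1 in enumerate(AA_ORDER):
            for j, a2 in enumerate(AA_ORDER):
                if j < i:
                    continue
                emit(a1, a2, table.values[i, j], table.mask[i, j])
    else:
        emit(table.provenance.get("group1", "g1"),
             table.provenance.get("group2", "g2"), table.values, table.mask)
    return "\n".join(rows) + "\n"


def potential_from_tsv(
    text: str,
    kbt: float = KBT_ROOM,
    scheme: BinningScheme = DEFAULT_SCHEME,
) -> PotentialTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header, body = lines[0], lines[1:]
    if not body:
        raise ValueError("empty potential table")
    flavor, region = body[0].split("\t")[:2]
    if flavor == "sd":
        values = np.zeros((N_AA, scheme.n_bins))
        mask = np.ones((N_AA, scheme.n_bins), dtype=bool)
    elif flavor == "sds":
        values = np.zeros((N_AA, N_AA, scheme.n_bins))
        mask = np.ones((N_AA, N_AA, scheme.n_bins), dtype=bool)
    else:
        values = np.zeros(scheme.n_bins)
        mask = np.ones(scheme.n_bins, dtype=bool)
    prov: dict = {}
    for ln in body:
        fl, reg, s1, s2, edge, val, msk = ln.split("\t")
        b = int(round((float(edge) - scheme.lower) / scheme.width))
        v, m = float(val), bool(int(msk))
        if fl == "sd":
            values[AA_INDEX[s1], b] = v
            mask[AA_INDEX[s1], b] = m
        elif fl == "sds":
            i, j = AA_INDEX[s1], AA_INDEX[s2]
            values[i, j, b] = values[j, i, b] = v
            mask[i, j, b] = mask[j, i, b] = m
        else:
            values[b] = v
            mask[b] = m
            prov = {"group1": s1, "group2": s2}
    return PotentialTable(flavor, region, kbt, values, mask, scheme, prov)
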