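"""TM/EM residue localization from per-residue folding energies.

Each residue gets a linear localization index

    I^i = a1*dG_sd^{i,TM} + a2*dG_sds^{i,TM} + a3*dG_sd^{i,EM}
        + a4*dG_sds^{i,EM} + a5*ln(N) + a6

smoothed along the chain over a five-residue window with a 1/2 prefactor,

    I_sm^i = 1/2 * (I^{i-2} + I^{i-1} + I^i + I^{i+1} + I^{i+2}),

and is called transmembrane iff I_sm^i <= a0. The seven parameters are fit
to maximize balanced accuracy: a two-stage procedure (logistic regression
for the weights, exhaustive threshold sweep for a0) because balanced
accuracy is piecewise constant in the weights and direct seven-parameter
optimization of it is ill-posed. Evaluation is pooled and per protein, with
AUC oriented so that low scores point toward TM, and supports a strict
leave-one-out protocol in which the target protein is excluded from both
potential derivation and parameter fitting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .contact_counts import DEFAULT_SCHEME, BinningScheme, accumulate_pair_counts
from .energetics import ENERGY_COLUMNS, loo_potentials, per_residue_energies
from .potentials import COUNT_THRESHOLD, KBT_ROOM
from .structure_io import EM, TM, LabeledStructure

FEATURE_COLUMNS = list(ENERGY_COLUMNS) + ["log_n"]


@dataclass
class LocalizationModel:
    """Seven parameters of the localization index and its decision rule."""

    alpha0: float  # decision threshold: I_sm <= alpha0 => TM
    alpha1: float  # weight on dG_sd^TM
    alpha2: float  # weight on dG_sds^TM
    alpha3: float  # weight on dG_sd^EM
    alpha4: float  # weight on dG_sds^EM
    alpha5: float  # weight on ln(N)
    alpha6: float  # intercept
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "alpha2", "alpha3", "alpha4", "alpha5", "alpha6"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3, self.alpha4, self.alpha5])

    def to_json(self) -> str:
        payload = {f"alpha{k}": getattr(self, f"alpha{k}") for k in range(7)}
        payload["metadata"] = self.metadata
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LocalizationModel":
        payload = json.loads(text)
        return cls(
            *(payload[f"alpha{k}"] for k in range(7)),
            metadata=payload.get("metadata", {}),
        )


def localization_index(
    features: pd.DataFrame | np.ndarray,
    model: LocalizationModel,
    n_residues: int | None = None,
) -> np.ndarray:
    """Raw index I^i for each residue row.

    ``features`` is either a frame with the four energy columns plus
    ``log_n``, or a (n, 4) energy array together with the protein length
    ``n_residues`` (natural log taken here).
    """
    if isinstance(features, pd.DataFrame):
        if "log_n" in features.columns:
            x = features[FEATURE_COLUMNS].to_numpy()
        else:
            if n_residues is None:
                n_residues = len(features)
            if n_residues < 1:
                raise ValueError("protein length must be >= 1")
            x = np.column_stack(
                [features[list(ENERGY_COLUMNS)].to_numpy(),
                 np.full(len(features), math.log(n_residues))]
            )
    else:
        x = np.asarray(features, dtype=float)
        if x.shape[1] == 4:
            if n_residues is None or n_residues < 1:
                raise ValueError("protein length must be >= 1")
            x = np.column_stack([x, np.full(len(x), math.log(n_residues))])
    return x @ model.weights + model.alpha6


def smooth_index(values: np.ndarray, chain_ids: np.ndarray | list) -> np.ndarray:
    """Five-residue window smoothing with the 1/2 prefactor.

    Windows never cross chain boundaries; at chain termini the truncated
    m-term sum is rescaled by 5/m so the index keeps the interior scale.
    """
    values = np.asarray(values, dtype=float)
    chain_ids = np.asarray(chain_ids)
    if len(values) == 0:
        raise ValueError("empty chain")
    out = np.empty_like(values)
    start = 0
    while start < len(values):
        end = start
        while end < len(values) and chain_ids[end] == chain_ids[start]:
            end += 1
        seg = values[start:end]
        n = len(seg)
        for i in range(n):
            lo, hi = max(0, i - 2), min(n, i + 3)
            m = hi - lo
            out[start + i] = 0.5 * (5.0 / m) * seg[lo:hi].sum()
        start = end
    return out


def balanced_accuracy(pred_tm: np.ndarray, true_tm: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 with TM as the positive class."""
    pred_tm = np.asarray(pred_tm, dtype=bool)
    true_tm = np.asarray(true_tm, dtype=bool)
    pos, neg = true_tm.sum(), (~true_tm).sum()
    if pos == 0 or neg == 0:
        raise ValueError("balanced accuracy needs both classes")
    sens = float((pred_tm & true_tm).sum() / pos)
    spec = float((~pred_tm & ~true_tm).sum() / neg)
    return 0.5 * (sens + spec)


def best_threshold(scores: np.ndarray, true_tm: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing balanced accuracy of the rule score <= t => TM.

    The sweep visits every distinct score; ties in balanced accuracy break
    toward the most balanced sensitivity/specificity split, and the returned
    threshold is the midpoint between the neighboring distinct scores.
    """
    scores = np.asarray(scores, dtype=float)
    true_tm = np.asarray(true_tm, dtype=bool)
    pos, neg = true_tm.sum(), (~true_tm).sum()
    if pos == 0 or neg == 0:
        raise ValueError("threshold fit needs both classes")
    order = np.argsort(scores, kind="mergesort")
    s, y = scores[order], true_tm[order]
    distinct_idx = np.nonzero(np.r_[np.diff(s) > 0, True])[0]
    cum_pos = np.cumsum(y)
    cum_neg = np.cumsum(~y)
    sens = cum_pos[distinct_idx] / pos          # score <= s[k] called TM
    spec = (neg - cum_neg[distinct_idx]) / neg
    bacc = 0.5 * (sens + spec)
    # candidate "call nothing TM" (threshold below the minimum score)
    cand_bacc = np.r_[0.5, bacc]
    cand_imbalance = np.r_[1.0, np.abs(sens - spec)]
    best = np.lexsort((cand_imbalance, -cand_bacc))[0]
    if best == 0:
        thr = float(s[0] - 1.0)
        return thr, 0.5
    k = distinct_idx[best - 1]
    if k + 1 < len(s):
        thr = 0.5 * (s[k] + s[k + 1])
    else:
        thr = float(s[k] + 1.0)
    return float(thr), float(cand_bacc[best])


def fit_localization_model(
    features: pd.DataFrame,
    seed: int = 0,
) -> LocalizationModel:
    """Fit the seven parameters on labeled residues.

    ``features`` needs the four energy columns, ``log_n``, a boolean
    ``is_tm`` label, and ``structure_id``/``chain`` keys for the window
    smoothing. Stage one fits unpenalized logistic regression on internally
    standardized features (so rescaling any feature leaves the predictions
    unchanged); stage two sweeps the decision threshold on the smoothed
    index to maximize training balanced accuracy.
    """
    y = features["is_tm"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data must contain both TM and EM residues")
    x = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    mu, sigma = x.mean(axis=0), x.std(axis=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    xs = (x - mu) / sigma
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                             tol=1e-10, random_state=seed)
    with warnings.catch_warnings():
        # on (near-)separable data the unpenalized likelihood has no finite
        # maximizer; the direction at the iteration cap is what we use
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(xs, y)
    w_std = clf.coef_[0]
    b_std = float(clf.intercept_[0])
    # back to raw feature scale; negate so low index means TM
    w_raw = w_std / sigma
    b_raw = b_std - float((w_std * mu / sigma).sum())
    alphas = -w_raw
    intercept = -b_raw

    idx = np.column_stack([x, np.ones(len(x))]) @ np.r_[alphas, intercept]
    chain_key = (features["structure_id"].astype(str) + "//"
                 + features["chain"].astype(str)).to_numpy()
    idx_sm = smooth_index(idx, chain_key)
    alpha0, train_bacc = best_threshold(idx_sm, y)
    return LocalizationModel(
        alpha0, *alphas, intercept,
        metadata={
            "optimizer": "logistic+bacc_sweep",
            "seed": seed,
            "n_train": int(len(y)),
            "train_bacc": train_bacc,
        },
    )


@dataclass
class ClassificationResult:
    """Metrics of TM/EM residue calls at a fixed threshold."""

    n: int
    n_tm: int
    n_em: int
    sensitivity: float
    specificity: float
    bacc: float
    auc: float

    @classmethod
    def from_scores(
        cls, scores: np.ndarray, true_tm: np.ndarray, alpha0: float
    ) -> "ClassificationResult":
        scores = np.asarray(scores, dtype=float)
        true_tm = np.asarray(true_tm, dtype=bool)
        if len(scores) != len(true_tm):
            raise ValueError("labels must be available for every scored residue")
        pred = scores <= alpha0
        pos, neg = int(true_tm.sum()), int((~true_tm).sum())
        sens = float((pred & true_tm).sum() / pos) if pos else float("nan")
        spec = float((~pred & ~true_tm).sum() / neg) if neg else float("nan")
        bacc = 0.5 * (sens + spec)
        if pos and neg:
            # low score points toward TM, the positive class
            auc = float(roc_auc_score(true_tm, -scores))
        else:
            auc = float("nan")
        return cls(len(scores), pos, neg, sens, spec, bacc, auc)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "n_tm": self.n_tm, "n_em": self.n_em,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "bacc": self.bacc, "auc": self.auc,
        }


def classify_and_evaluate(
    scores: np.ndarray,
    true_tm: np.ndarray,
    alpha0: float,
    groups: np.ndarray | None = None,
) -> dict[str, ClassificationResult]:
    """Pooled metrics, optionally broken down by a grouping key
    (e.g. topology class)."""
    results = {"all": ClassificationResult.from_scores(scores, true_tm, alpha0)}
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            sel = groups == g
            results[str(g)] = ClassificationResult.from_scores(
                np.asarray(scores)[sel], np.asarray(true_tm)[sel], alpha0
            )
    return results


@dataclass
class BenchmarkReport:
    pooled: ClassificationResult
    by_topology: dict[str, ClassificationResult]
    per_protein: pd.DataFrame
    residues: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "pooled": self.pooled.to_dict(),
                "by_topology": {k: v.to_dict() for k, v in self.by_topology.items()},
                "per_protein": self.per_protein.to_dict(orient="records"),
            },
            indent=2,
        )


def _loo_feature_table(
    structures: list[LabeledStructure],
    scheme: BinningScheme,
    kbt: float,
    threshold: float,
    inter_chain: bool,
) -> pd.DataFrame:
    """Per-residue energies with each protein scored under potentials that
    exclude itself (the strict part of the protocol)."""
    counts = {
        region: accumulate_pair_counts(structures, region, scheme, inter_chain)
        for region in (TM, EM)
    }
    frames = []
    for st in structures:
        tables = {}
        for region in (TM, EM):
            for flavor in ("sd", "sds"):
                t = loo_potentials(counts[region], st.structure_id, flavor,
                                   kbt, threshold)
                assert st.structure_id in t.provenance["excluded"]
                tables[(flavor, region)] = t
        profile = per_residue_energies(st, tables, inter_chain)
        f = profile.frame.copy()
        f["structure_id"] = st.structure_id
        f["topology"] = st.topology_class
        f["log_n"] = math.log(len(st.residues))
        f["is_tm"] = f["region"] == TM
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def run_loo_benchmark(
    structures: list[LabeledStructure],
    seed: int = 0,
    scheme: BinningScheme = DEFAULT_SCHEME,
    kbt: float = KBT_ROOM,
    threshold: float = COUNT_THRESHOLD,
    inter_chain: bool = False,
) -> BenchmarkReport:
    """Strict leave-one-out benchmark of TM/EM residue localization.

    For every target protein, the potentials are derived without it, the
    seven index parameters are fit on the remaining proteins' residues
    (themselves scored under their own leave-one-out potentials), and only
    then is the target scored. Pooled metrics aggregate all held-out
    residues; proteins lacking one of the two classes are scored but
    excluded from the per-protein metric table.
    """
    if len(structures) < 3:
        raise ValueError("the leave-one-out benchmark needs at least 3 proteins")
    feats = _loo_feature_table(structures, scheme, kbt, threshold, inter_chain)

    rows = []
    scored = []
    for st in structures:
        sid = st.structure_id
        train = feats[feats["structure_id"] != sid]
        test = feats[feats["structure_id"] == sid]
        model = fit_localization_model(train, seed=seed)
        idx = localization_index(test, model)
        idx_sm = smooth_index(idx, test["chain"].to_numpy())
        part = test[["structure_id", "chain", "seq_index", "aa", "region",
                     "topology", "is_tm"]].copy()
        part["index"] = idx
        part["index_sm"] = idx_sm
        part["alpha0"] = model.alpha0
        part["pred_tm"] = idx_sm <= model.alpha0
        scored.append(part)
        y = test["is_tm"].to_numpy(dtype=bool)
        if y.any() and not y.all():
            res = ClassificationResult.from_scores(idx_sm, y, model.alpha0)
            rows.append({"structure_id": sid, "topology": st.topology_class,
                         **res.to_dict()})
    residues = pd.concat(scored, ignore_index=True)

    # pooled metrics: per-target thresholds for the calls, pooled scores for AUC
    true_tm = residues["is_tm"].to_numpy(dtype=bool)
    pred_tm = residues["pred_tm"].to_numpy(dtype=bool)
    pos, neg = int(true_tm.sum()), int((~true_tm).sum())
    sens = float((pred_tm & true_tm).sum() / pos)
    spec = float((~pred_tm & ~true_tm).sum() / neg)
    pooled = ClassificationResult(
        n=len(residues), n_tm=pos, n_em=neg,
        sensitivity=sens, specificity=spec, bacc=0.5 * (sens + spec),
        auc=float(roc_auc_score(true_tm, -residues["index_sm"].to_numpy())),
    )
    by_topology = {}
    for topo in residues["topology"].unique():
        sel = residues["topology"] == topo
        y = residues.loc[sel, "is_tm"].to_numpy(dtype=bool)
        p = residues.loc[sel, "pred_tm"].to_numpy(dtype=bool)
        s = residues.loc[sel, "index_sm"].to_numpy()
        tp, tn = int(y.sum()), int((~y).sum())
        se = float((p & y).sum() / tp) if tp else float("nan")
        sp = float((~p & ~y).sum() / tn) if tn else float("nan")
        by_topology[str(topo)] = ClassificationResult(
            n=int(sel.sum()), n_tm=tp, n_em=tn, sensitivity=se, specificity=sp,
            bacc=0.5 * (se + sp),
            auc=float(roc_auc_score(y, -s)) if tp and tn else float("nan"),
        )
    return BenchmarkReport(pooled, by_topology, pd.DataFrame(rows), residues)
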