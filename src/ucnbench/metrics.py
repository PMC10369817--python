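"""Explainability and predictive metrics with per-target aggregation.

*Global direction* (per pair): does the difference of the mean attribution
over the two compounds' uncommon atoms have the same sign as the observed
activity difference?  *Color agreement* (per compound): fraction of uncommon
atoms whose attribution sign matches the +/-1 ground-truth color.  Signs are
taken with a tolerance: |x| < eps counts as sign 0, which can never match the
sign of a post-filter activity difference, so exact-zero attributions are
conservatively counted as failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .attribution import Attribution
from .pairing import CompoundPair

SIGN_EPS = 1e-12

MCS_THRESHOLD_GRID = (0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.95)


def _sign(x: float, eps: float = SIGN_EPS) -> int:
    if abs(x) < eps:
        return 0
    return 1 if x > 0 else -1


@dataclass
class PairDirectionResult:
    pair_id: str
    g_dir: int  # 0 or 1
    mean_uncommon_i: float
    mean_uncommon_j: float


@dataclass
class ColorAgreementResult:
    compound_id: str
    per_atom_agreement: np.ndarray  # binary, over uncommon atoms (sorted index order)
    mean: float


@dataclass
class TargetReport:
    target_id: str
    n_test_pairs: int
    g_dir_mean: Optional[float] = None
    g_atom_mean: Optional[float] = None
    rmse: Optional[float] = None
    pcc: Optional[float] = None
    n_test_compounds: int = 0


def global_direction(
    pair: CompoundPair, attr_i: Attribution, attr_j: Attribution
) -> PairDirectionResult:
    """Binary sign-preservation metric for one pair (more potent compound first)."""
    if not pair.evaluable:
        raise ValueError(f"pair {pair.pair_id} has an empty uncommon set; not evaluable")
    mi = float(np.mean(attr_i.atom_scores[sorted(pair.uncommon_i)]))
    mj = float(np.mean(attr_j.atom_scores[sorted(pair.uncommon_j)]))
    ok = _sign(mi - mj) == _sign(pair.delta_activity) and _sign(pair.delta_activity) != 0
    return PairDirectionResult(pair.pair_id, int(ok), mi, mj)


def color_agreement(
    pair: CompoundPair, compound_side: str, attr: Attribution
) -> ColorAgreementResult:
    """Per-atom sign agreement with the +/-1 ground truth on uncommon atoms."""
    if compound_side not in ("i", "j"):
        raise ValueError("compound_side must be 'i' or 'j'")
    record = pair.record_i if compound_side == "i" else pair.record_j
    uncommon = pair.uncommon_i if compound_side == "i" else pair.uncommon_j
    truth = pair.ground_truth_i if compound_side == "i" else pair.ground_truth_j
    if truth is None:
        raise ValueError(f"pair {pair.pair_id} has no ground-truth coloring")
    idx = sorted(uncommon)
    if not idx:
        raise ValueError(f"compound {record.compound_id} has no uncommon atoms in this pair")
    agree = np.array(
        [1 if _sign(attr.atom_scores[v]) == int(truth[v]) else 0 for v in idx], dtype=np.int64
    )
    return ColorAgreementResult(record.compound_id, agree, float(agree.mean()))


# ---------------------------------------------------------------------------
# predictive metrics
# ---------------------------------------------------------------------------


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("rmse needs equal-length, non-empty inputs")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pcc(y: Sequence[float], yhat: Sequence[float]) -> Optional[float]:
    """Pearson correlation; None when undefined (zero variance)."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("pcc needs equal-length inputs of size >= 2")
    if np.std(y) == 0 or np.std(yhat) == 0:
        return None
    return float(np.corrcoef(y, yhat)[0, 1])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate(
    reports: Sequence[TargetReport],
    weights: str = "pairs",
) -> Dict[str, Dict[str, Optional[float]]]:
    """Simple mean, weighted mean and standard deviation per metric.

    ``weights`` selects the weighting variable: "pairs" (test-pair counts,
    the default) or "compounds" (test-compound counts).
    """
    if not reports:
        raise ValueError("aggregate needs at least one target report")
    if weights == "pairs":
        w_all = np.asarray([r.n_test_pairs for r in reports], dtype=np.float64)
    elif weights == "compounds":
        w_all = np.asarray([r.n_test_compounds for r in reports], dtype=np.float64)
    else:
        raise ValueError("weights must be 'pairs' or 'compounds'")

    out: Dict[str, Dict[str, Optional[float]]] = {}
    for name in ("g_dir_mean", "g_atom_mean", "rmse", "pcc"):
        vals, w = [], []
        for r, wr in zip(reports, w_all):
            v = getattr(r, name)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                vals.append(v)
                w.append(wr)
        if not vals:
            out[name] = {"simple": None, "weighted": None, "std": None}
            continue
        vals_a, w_a = np.asarray(vals), np.asarray(w)
        weighted = float(np.sum(vals_a * w_a) / np.sum(w_a)) if np.sum(w_a) > 0 else None
        out[name] = {
            "simple": float(vals_a.mean()),
            "weighted": weighted,
            "std": float(vals_a.std(ddof=0)),
        }
    return out


def stratify(
    results: pd.DataFrame,
    by: str,
    mcs_grid: Sequence[float] = MCS_THRESHOLD_GRID,
    diversity_bins: Sequence[float] = (0.0, 0.2, 0.5, 1.0),
    metric: str = "g_dir",
) -> pd.DataFrame:
    """Metric summaries per stratum of a per-pair results table.

    ``results`` needs columns ``mcs_fraction``, ``n_sites`` and/or
    ``diversity`` depending on ``by``, plus the metric column.  MCS strata are
    cumulative ("minimum shared" fraction >= threshold); substitution-site
    strata are {1} vs {>=2}; diversity strata are half-open bins.
    """
    rows = []
    if by == "mcs_threshold":
        for thr in mcs_grid:
            sub = results[results["mcs_fraction"] >= thr]
            rows.append(_stratum_row(f">={thr:g}", sub, metric))
    elif by == "n_sites":
        rows.append(_stratum_row("1", results[results["n_sites"] == 1], metric))
        rows.append(_stratum_row(">=2", results[results["n_sites"] >= 2], metric))
    elif by == "diversity_bin":
        edges = list(diversity_bins)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = results[(results["diversity"] >= lo) & (results["diversity"] < hi)]
            rows.append(_stratum_row(f"[{lo:g},{hi:g})", sub, metric))
    else:
        raise ValueError("by must be 'mcs_threshold', 'n_sites' or 'diversity_bin'")
    return pd.DataFrame(rows)


def _stratum_row(label: str, sub: pd.DataFrame, metric: str) -> Dict:
    return {
        "stratum": label,
        "n": int(len(sub)),
        metric: float(sub[metric].mean()) if len(sub) else None,
    }
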