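"""Feature screening and differential statistics between author groups.

Two independent concerns live here:

* the *inclusion rule* used before classification — keep features present
  in at least ``min_present`` real samples and absent from every solvent
  blank (:func:`filter_features`);
* the *differential analysis* — impute missing intensities with a small
  constant, log-transform, Welch t-test per feature between the two author
  groups, and Benjamini–Hochberg FDR correction
  (:func:`differential_analysis`).

Differential statistics are computed on the unfiltered matrix so the
blank-presence flag of each significant feature stays meaningful; the
diagnostic shortlist (:func:`select_diagnostic`) then keeps the q < 0.05,
blank-free features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment import PeakMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

DIFFERENTIAL_COLUMNS = [
    "feature_mz",
    "n_a",
    "n_b",
    "t_stat",
    "p_value",
    "q_value",
    "blank_free",
    "mean_log_a",
    "mean_log_b",
]


@dataclass(frozen=True)
class ScreenParams:
    """Screening parameters.

    min_present
        Minimum number of non-blank samples a feature must appear in.
    q_threshold
        FDR level for the diagnostic shortlist.
    impute_value
        Constant imputed into missing intensities before logging
        (intensities are on the per-mille normalized scale).
    log_base
        ``10`` or ``"e"``; the t statistic is invariant to this choice.
    """

    min_present: int = 3
    q_threshold: float = 0.05
    impute_value: float = 1e-5
    log_base: object = 10

    def __post_init__(self) -> None:
        if self.min_present < 1:
            raise ValidationError("min_present must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must be in (0, 1)")
        if self.impute_value <= 0:
            raise ValidationError("impute_value must be > 0")
        if self.log_base not in (10, "e"):
            raise ValidationError("log_base must be 10 or 'e'")

    def log(self, x: np.ndarray) -> np.ndarray:
        return np.log10(x) if self.log_base == 10 else np.log(x)


def filter_features(
    matrix: PeakMatrix, params: ScreenParams = ScreenParams()
) -> PeakMatrix:
    """Apply the presence/blank inclusion rule.

    Keeps features with >= ``min_present`` measurements among non-blank
    samples and none among blanks.  Columns are unchanged.
    """
    presence = matrix.presence()
    blanks = matrix.blank_ids()
    nonblank = matrix.nonblank_ids()
    if not blanks:
        logger.warning("no blank samples in manifest; blank rule is vacuous")
    n_present = presence[nonblank].sum(axis=1).to_numpy()
    n_blank = (
        presence[blanks].sum(axis=1).to_numpy() if blanks else np.zeros(matrix.n_features)
    )
    mask = (n_present >= params.min_present) & (n_blank == 0)
    return matrix.subset_features(mask)


def impute_and_log(
    matrix: PeakMatrix, params: ScreenParams = ScreenParams()
) -> PeakMatrix:
    """Impute missing cells with ``impute_value`` and log-transform.

    The result has no missing cells.  Observed non-positive intensities
    are an error (they cannot be logged and should not occur after
    total-signal normalization).
    """
    vals = matrix.values.to_numpy(copy=True)
    observed = ~np.isnan(vals)
    if np.any(vals[observed] <= 0):
        raise ValidationError("non-positive observed intensity; cannot log")
    vals[~observed] = params.impute_value
    return PeakMatrix(
        feature_mz=matrix.feature_mz.copy(),
        values=pd.DataFrame(params.log(vals), columns=matrix.sample_ids),
        samples=list(matrix.samples),
    )


def t_test_feature(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) on logged intensities.

    Groups with fewer than two values yield ``(nan, nan)`` — the feature
    is untestable.  When both groups have zero variance the test is
    degenerate: p = 1 if the means agree, else p = 0 with infinite t.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    Missing p-values propagate to missing q-values and do not count
    toward the number of tests.  p outside [0, 1] is an error.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def differential_analysis(
    matrix: PeakMatrix,
    params: ScreenParams = ScreenParams(),
    substrate: str | None = None,
) -> pd.DataFrame:
    """Per-feature Welch t-test between the two author groups, with BH FDR.

    Runs on the *unfiltered* matrix: every feature is tested and carries a
    ``blank_free`` flag (no measurement in any solvent blank), so the
    diagnostic shortlist can be drawn afterwards.  ``substrate`` restricts
    the comparison to one stratum (e.g. ``"ink"``); the default pools
    strata, mirroring the combined comparison.

    Missing intensities are imputed (``impute_value``) and values logged
    before testing; ``n_a``/``n_b`` count actual measurements.
    """
    groups = sorted({s.author for s in matrix.samples if not s.is_blank})
    if len(groups) != 2:
        raise ValidationError(
            f"differential analysis needs exactly two author groups, got {groups}"
        )
    ga, gb = groups

    def _ids(author: str) -> list[str]:
        return [
            s.sample_id
            for s in matrix.samples
            if not s.is_blank
            and s.author == author
            and (substrate is None or s.substrate == substrate)
        ]

    ids_a, ids_b = _ids(ga), _ids(gb)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each author group needs >= 2 samples")

    logged = impute_and_log(matrix, params)
    blanks = matrix.blank_ids()
    presence = matrix.presence()
    blank_free = (
        ~presence[blanks].any(axis=1) if blanks else pd.Series(True, index=presence.index)
    )

    rows = []
    la = logged.values[ids_a].to_numpy()
    lb = logged.values[ids_b].to_numpy()
    na = presence[ids_a].sum(axis=1).to_numpy()
    nb = presence[ids_b].sum(axis=1).to_numpy()
    import warnings

    for i in range(matrix.n_features):
        with warnings.catch_warnings():
            # near-identical groups trip scipy's catastrophic-cancellation
            # warning; the degenerate exact-equality case is handled above
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = t_test_feature(la[i], lb[i])
        rows.append(
            {
                "feature_mz": matrix.feature_mz[i],
                "n_a": int(na[i]),
                "n_b": int(nb[i]),
                "t_stat": t,
                "p_value": p,
                "blank_free": bool(blank_free.iloc[i]),
                "mean_log_a": float(la[i].mean()),
                "mean_log_b": float(lb[i].mean()),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_correct(out["p_value"].to_numpy())
    return out[DIFFERENTIAL_COLUMNS]


def select_diagnostic(
    results: pd.DataFrame, params: ScreenParams = ScreenParams()
) -> np.ndarray:
    """Diagnostic features: q < threshold and absent from every blank.

    Returns feature m/z values sorted by ascending q.
    """
    mask = (results["q_value"] < params.q_threshold) & results["blank_free"]
    hits = results.loc[mask].sort_values("q_value", kind="stable")
    return hits["feature_mz"].to_numpy()
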