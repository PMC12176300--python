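"""Longitudinal fold-change statistics for cycle-stratified immune measures.

Per-animal fold change (each animal its own reference, controlling for
animal-to-animal variation), a one-sample Wilcoxon signed-rank test of the
folds against 1, Benjamini–Hochberg FDR adjustment across phases or
populations, fold-based ordering of analyte panels, and the strict
significance filter for differential-expression tables
(FDR < 0.05 and |log2FC| > 1).

The signed-rank test uses the exact null distribution by full enumeration
of the 2^n sign assignments when n <= 15 and the normal approximation with
tie correction for larger n.  Zero differences (fold exactly 1) are dropped
before ranking by default; the Pratt convention is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_MAX_N = 15


def fold_change_vs_reference(
    data: pd.DataFrame,
    reference: str | None = None,
    *,
    animal_col: str = "animal_id",
    phase_col: str = "phase",
    population_col: str = "population",
    value_col: str = "value",
    day_col: str | None = None,
) -> pd.DataFrame:
    """Per-animal fold change of each measurement over its reference value.

    For every (animal, population) the reference value is the mean of that
    animal's measurements at the ``reference`` phase; each row's fold is
    value / reference.  With ``reference=None`` the reference phase is each
    animal's first sampled phase (ordered by ``day_col`` when given, else by
    row order).  Groups whose reference value is missing or zero are
    excluded with a logged warning; the exclusion count is stored in
    ``result.attrs["n_excluded"]``.
    """
    required = [animal_col, phase_col, population_col, value_col]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"fold-change input is missing columns: {missing}")
    out_frames = []
    n_excluded = 0
    for (animal, population), grp in data.groupby(
        [animal_col, population_col], sort=True
    ):
        if day_col is not None:
            grp = grp.sort_values(day_col, kind="stable")
        ref_phase = reference
        if ref_phase is None:
            ref_phase = grp.iloc[0][phase_col]
        ref_rows = grp[grp[phase_col] == ref_phase]
        ref_value = ref_rows[value_col].mean() if len(ref_rows) else np.nan
        if not np.isfinite(ref_value) or ref_value <= 0:
            n_excluded += len(grp)
            logger.warning(
                "excluding animal=%s population=%s: reference phase %r value is "
                "missing or non-positive",
                animal,
                population,
                ref_phase,
            )
            continue
        folds = grp[value_col].to_numpy(dtype=float) / float(ref_value)
        frame = pd.DataFrame(
            {
                "animal_id": animal,
                "phase": grp[phase_col].to_numpy(),
                "population": population,
                "fold": folds,
                "reference_phase": ref_phase,
            }
        )
        if day_col is not None:
            frame["day"] = grp[day_col].to_numpy()
        out_frames.append(frame)
    if out_frames:
        result = pd.concat(out_frames, ignore_index=True)
    else:
        result = pd.DataFrame(
            columns=["animal_id", "phase", "population", "fold", "reference_phase"]
        )
    result.attrs["n_excluded"] = n_excluded
    return result


@dataclass(frozen=True)
class TestResult:
    """One-sample signed-rank test outcome for a (population, phase) cell."""

    population: str
    phase: str
    statistic: float
    p_raw: float
    n: int
    method: str
    degenerate: bool = False
    p_adjusted: float | None = None


@lru_cache(maxsize=32)
def _sign_matrix(n: int) -> np.ndarray:
    # all 2^n subsets of {positive differences}, as a boolean matrix
    idx = np.arange(2**n, dtype=np.uint32)
    return (idx[:, None] >> np.arange(n)[None, :]) & 1


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided p by enumerating all sign assignments of the ranks.

    The null distribution of W (sum of positive-difference ranks) is
    symmetric about mu = sum(ranks)/2 even with average ranks, so the
    two-sided p is P(|W - mu| >= |w_obs - mu|).
    """
    n = ranks.size
    signs = _sign_matrix(n)
    w_null = signs @ ranks
    mu = 0.5 * ranks.sum()
    c = abs(w_obs - mu)
    return float(np.mean(np.abs(w_null - mu) >= c - 1e-9))


def _approx_two_sided_p(ranks: np.ndarray, w_obs: float, d_abs: np.ndarray) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = ranks.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(d_abs, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 1.0
    z = max(abs(w_obs - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(z))


def test_fold_vs_unity(
    folds,
    population: str = "",
    phase: str = "",
    zero_method: str = "drop",
) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test of folds against 1.

    ``zero_method="drop"`` removes folds exactly equal to 1 before ranking
    (Wilcoxon's convention); ``"pratt"`` ranks them but drops their
    contribution to the statistic.  All-unity input returns p = 1 with a
    degenerate flag.
    """
    folds = np.asarray(list(folds), dtype=float)
    if folds.size == 0:
        raise ValueError("need at least one fold value")
    if not np.all(np.isfinite(folds)):
        raise ValueError("folds must be finite")
    d = folds - 1.0
    if zero_method == "pratt":
        nz = d[d != 0]
        if nz.size == 0:
            return TestResult(population, phase, 0.0, 1.0, 0, "degenerate", True)
        res = sps.wilcoxon(
            d, zero_method="pratt", correction=False, alternative="two-sided",
            method="approx",
        )
        return TestResult(
            population, phase, float(res.statistic), float(res.pvalue),
            int(nz.size), "pratt-approx",
        )
    if zero_method != "drop":
        raise ValueError("zero_method must be 'drop' or 'pratt'")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(population, phase, 0.0, 1.0, 0, "degenerate", True)
    d_abs = np.abs(d)
    ranks = sps.rankdata(d_abs)
    w = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        p = _approx_two_sided_p(ranks, w, d_abs)
        method = "approx"
    return TestResult(population, phase, w, min(p, 1.0), n, method)


# these are library entry points, not pytest cases, despite the names
TestResult.__test__ = False
test_fold_vs_unity.__test__ = False


def adjust_fdr(p_values, method: str = "bh") -> np.ndarray:
    """FDR-adjusted p-values, order-preserving with the input.

    ``"bh"`` is the Benjamini–Hochberg step-up procedure; ``"bky"`` the
    two-stage Benjamini–Krieger–Yekutieli variant (the GraphPad default).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "bky": "fdr_tsbky"}.get(method)
    if key is None:
        raise ValueError("method must be 'bh' or 'bky'")
    adjusted = multipletests(p, alpha=0.05, method=key)[1]
    return np.minimum(adjusted, 1.0)


def test_folds_by_group(
    fold_table: pd.DataFrame,
    *,
    population_col: str = "population",
    phase_col: str = "phase",
    fold_col: str = "fold",
    exclude_reference: bool = True,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Signed-rank tests of fold vs 1 for every (population, phase) cell,
    with FDR adjustment across all cells.

    Reference-phase rows (fold identically 1 by construction) are excluded
    from testing by default.
    """
    df = fold_table
    if exclude_reference and "reference_phase" in df.columns:
        df = df[df[phase_col] != df["reference_phase"]]
    rows = []
    for (population, phase), grp in df.groupby([population_col, phase_col], sort=True):
        res = test_fold_vs_unity(
            grp[fold_col].to_numpy(), population=str(population), phase=str(phase)
        )
        rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["population", "phase", "n", "statistic", "p_raw", "p_adjusted",
                     "method", "degenerate"]
        )
    out = pd.DataFrame(
        {
            "population": [r.population for r in rows],
            "phase": [r.phase for r in rows],
            "n": [r.n for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "method": [r.method for r in rows],
            "degenerate": [r.degenerate for r in rows],
        }
    )
    out["p_adjusted"] = adjust_fdr(out["p_raw"].to_numpy(), method=fdr_method)
    return out[["population", "phase", "n", "statistic", "p_raw", "p_adjusted",
                "method", "degenerate"]]


test_folds_by_group.__test__ = False


def order_by_fold_increase(
    panel: pd.DataFrame,
    *,
    analyte_col: str = "population",
    fold_col: str = "fold",
) -> list[str]:
    """Analytes sorted by greatest mean fold increase, ties alphabetical."""
    if panel.empty:
        return []
    summary = panel.groupby(analyte_col, sort=True)[fold_col].mean().reset_index()
    summary = summary.sort_values(
        by=[fold_col, analyte_col], ascending=[False, True], kind="stable"
    )
    return summary[analyte_col].tolist()


def filter_significant_genes(
    table: pd.DataFrame,
    *,
    fdr_col: str = "FDR",
    lfc_col: str = "log2FC",
    max_fdr: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> pd.DataFrame:
    """Rows with FDR strictly below 0.05 and |log2FC| strictly above 1."""
    mask = (table[fdr_col] < max_fdr) & (table[lfc_col].abs() > min_abs_lfc)
    return table[mask].reset_index(drop=True)
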