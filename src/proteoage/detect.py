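"""Detection of age-variant proteins.

For each protein and SILAC pair, the replicate log2 ratios are compared by
one-way ANOVA against the pooled replicate ratios of k randomly sampled
age-invariant control proteins. Because ratio measurement error grows as
intensity falls, controls are drawn from the same log10-intensity quantile
bin as the tested protein. Per-pair p values are corrected for multiple
testing (Benjamini-Hochberg), a protein-level combined p value is formed
across the three pairs, and the dataset-wide mean +/- 1.96 SD ratio band
is reported alongside as a descriptive flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import RatioMatrix
from .simulate import PAIRS


@dataclass
class DetectionParams:
    """Tuning parameters of the age-variance test.

    ``control_tau`` is the "close to zero" bound defining age-invariant
    control candidates: a control's mean log2 ratio must stay within
    ``+/- control_tau`` in every SILAC pair. The default 0.5 keeps the
    control pool essentially untruncated relative to measurement noise,
    which the null calibration requires (see the methods note); proteins
    with genuine ~2-fold age changes are still excluded.

    ``protein_rule`` sets how the three per-pair tests combine into one
    per-protein significance call: ``"simes"`` (default) combines the pair
    p values by Simes' method and BH-corrects across proteins, keeping the
    protein-level false-discovery rate at ``alpha``; ``"union"`` flags a
    protein when any single pair's BH-corrected q falls below ``alpha``.
    """

    band_multiplier: float = 1.96
    control_tau: float = 0.5
    controls_per_test: int = 20
    intensity_bins: int = 10
    alpha: float = 0.05
    fdr_method: str = "bh"
    protein_rule: str = "simes"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_tau <= 0:
            raise ValueError("control_tau must be positive")
        if self.controls_per_test < 2:
            raise ValueError("controls_per_test must be at least 2")
        if self.intensity_bins < 1:
            raise ValueError("intensity_bins must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.protein_rule not in ("simes", "union"):
            raise ValueError("protein_rule must be 'simes' or 'union'")


def confidence_band(
    matrix: RatioMatrix, pair: str, multiplier: float = 1.96
) -> tuple[float, float, float, float]:
    """Dataset-wide (mean, SD, lower, upper) of per-protein mean log2 ratios."""
    means = matrix.mean_log2()[pair].dropna()
    if len(means) < 3:
        raise ValueError(f"fewer than 3 proteins with complete {pair} ratios")
    mu = float(means.mean())
    sd = float(means.std(ddof=1))
    return mu, sd, mu - multiplier * sd, mu + multiplier * sd


class _ControlPool:
    """Eligible age-invariant controls stratified by intensity bin.

    Eligibility: complete replicate values in every SILAC pair and all
    per-pair mean log2 ratios within +/- tau. Intensity bins are quantile
    bins of log10 reference intensity over the whole matrix.
    """

    def __init__(self, matrix: RatioMatrix, params: DetectionParams):
        means = matrix.mean_log2(require_complete=True)
        complete_all = means.notna().all(axis=1)
        near_zero = (means.abs() <= params.control_tau).all(axis=1)
        self.eligible = (complete_all & near_zero).to_numpy()
        if self.eligible.sum() < 2:
            raise ValueError(
                "fewer than 2 eligible age-invariant controls in the dataset"
            )
        log10_ref = np.log10(matrix.ref_intensity.to_numpy(float))
        edges = np.quantile(
            log10_ref, np.linspace(0, 1, params.intensity_bins + 1)[1:-1]
        )
        self.bins = np.searchsorted(edges, log10_ref, side="right")
        self.n_bins = params.intensity_bins
        self.k = params.controls_per_test
        self._by_bin = [
            np.flatnonzero(self.eligible & (self.bins == b))
            for b in range(self.n_bins)
        ]
        self._warned = False

    def sample(self, target_index: int, rng: np.random.Generator) -> np.ndarray:
        """k control row indices for a target row, widening bins on shortage."""
        b = self.bins[target_index]
        width = 0
        while True:
            lo, hi = b - width, b + width
            candidates = np.concatenate(
                [self._by_bin[x] for x in range(max(0, lo), min(self.n_bins, hi + 1))]
            )
            candidates = candidates[candidates != target_index]
            if len(candidates) >= self.k or (lo <= 0 and hi >= self.n_bins - 1):
                break
            width += 1
        if width > 0 and not self._warned:
            warnings.warn(
                "control shortage in some intensity bins; widened to adjacent bins",
                stacklevel=3,
            )
            self._warned = True
        if len(candidates) <= self.k:
            return candidates
        return rng.choice(candidates, size=self.k, replace=False)


def sample_matched_controls(
    target_id: str,
    matrix: RatioMatrix,
    params: DetectionParams,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Intensity-matched age-invariant control ids for one target protein."""
    if target_id not in matrix.proteins:
        raise KeyError(f"unknown protein {target_id!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pool = _ControlPool(matrix, params)
    idx = pool.sample(matrix.proteins.get_loc(target_id), rng)
    return list(matrix.proteins[idx])


def anova_p(target_ratios, control_ratios) -> tuple[float, float]:
    """One-way ANOVA of a target's replicate log2 ratios against pooled controls.

    Returns (F, p) with p from the F distribution on (1, n - 2) degrees of
    freedom. Degenerate conventions: zero within-group variance with equal
    group means gives p = 1; with unequal means, p = 0 (warned).
    """
    t = np.asarray(target_ratios, dtype=float)
    c = np.asarray(control_ratios, dtype=float)
    t = t[np.isfinite(t)]
    c = c[np.isfinite(c)]
    if len(t) < 2 or len(c) < 2:
        raise ValueError("each group needs at least 2 finite values")
    n1, n2 = len(t), len(c)
    m1, m2 = t.mean(), c.mean()
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = float(((t - m1) ** 2).sum() + ((c - m2) ** 2).sum())
    dof2 = n1 + n2 - 2
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means; p = 0")
        return np.inf, 0.0
    f = float(ssb / (ssw / dof2))
    p = float(stats.f.sf(f, 1, dof2))
    return f, p


def fdr_correct(pvals, method: str = "bh") -> np.ndarray:
    """FDR correction (Benjamini-Hochberg step-up by default); NaN-aware."""
    methods = {"bh": "fdr_bh", "by": "fdr_by"}
    if method not in methods:
        raise ValueError(f"unknown FDR method {method!r}")
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method=methods[method])[1]
    return q


@dataclass
class AgeVarianceResult:
    """Per-protein, per-pair test results plus protein-level calls.

    ``table`` is long format (protein, pair, fold_change, F, p, q,
    outside_band, direction); ``proteins`` carries the per-protein
    combined p/q, overall significance, and overall direction; ``bands``
    maps each pair to its (mean, sd, lower, upper) descriptive band.
    """

    table: pd.DataFrame
    proteins: pd.DataFrame
    bands: dict[str, tuple[float, float, float, float]]
    params: DetectionParams

    @property
    def significant_ids(self) -> pd.Index:
        return self.proteins.index[self.proteins["significant"]]


def _simes(pmat: np.ndarray) -> np.ndarray:
    """Simes combined p value per row over the finite entries."""
    out = np.full(pmat.shape[0], np.nan)
    for i, row in enumerate(pmat):
        p = np.sort(row[np.isfinite(row)])
        m = len(p)
        if m:
            out[i] = min(1.0, float((m * p / np.arange(1, m + 1)).min()))
    return out


def detect_age_variant(
    matrix: RatioMatrix, params: DetectionParams | None = None
) -> AgeVarianceResult:
    """Run the full control-resampled ANOVA screen over a ratio matrix.

    For every protein one control set is drawn (intensity-matched, used
    for all three pairs); each pair with complete replicate values is
    tested against the pooled control values for that pair. Per-pair
    p values are BH-corrected within the pair's family; the protein-level
    call follows ``params.protein_rule``. Control-sampling failures are
    propagated as NaN results for the affected protein, not as a run
    abort.
    """
    if params is None:
        params = DetectionParams()
    rng = np.random.default_rng(params.seed)
    n = len(matrix.proteins)
    n_rep = matrix.n_replicates
    pool = _ControlPool(matrix, params)

    k = params.controls_per_test
    ctrl_idx = np.full((n, k), -1, dtype=int)
    for i in range(n):
        drawn = pool.sample(i, rng)
        ctrl_idx[i, : len(drawn)] = drawn
    ctrl_valid = ctrl_idx >= 0

    pair_values = {p: matrix.pair_frame(p).to_numpy(float) for p in PAIRS}
    records: dict[str, dict[str, np.ndarray]] = {}
    for pair in PAIRS:
        v = pair_values[pair]  # n x n_rep
        complete = np.isfinite(v).all(axis=1)
        cv = v[np.where(ctrl_valid, ctrl_idx, 0)]  # n x k x n_rep
        cv = np.where(ctrl_valid[:, :, None], cv, np.nan)
        cflat = cv.reshape(n, -1)
        n2 = np.isfinite(cflat).sum(axis=1)

        m1 = v.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m2 = np.nanmean(cflat, axis=1)
            ssw_c = np.nansum((cflat - m2[:, None]) ** 2, axis=1)
        grand = (n_rep * m1 + n2 * m2) / (n_rep + n2)
        ssb = n_rep * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
        ssw = ((v - m1[:, None]) ** 2).sum(axis=1) + ssw_c
        dof2 = n_rep + n2 - 2

        valid = complete & (n2 >= 2)
        fstat = np.full(n, np.nan)
        pval = np.full(n, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat[valid] = ssb[valid] / (ssw[valid] / dof2[valid])
        degenerate = valid & (ssw == 0.0)
        pval[valid] = stats.f.sf(fstat[valid], 1, dof2[valid])
        pval[degenerate & (ssb == 0.0)] = 1.0
        pval[degenerate & (ssb > 0.0)] = 0.0

        fold = np.where(complete, m1, np.nan)
        records[pair] = {"fold_change": fold, "F": fstat, "p": pval}

    bands = {p: confidence_band(matrix, p, params.band_multiplier) for p in PAIRS}

    rows = []
    pmat = np.column_stack([records[p]["p"] for p in PAIRS])
    qmat = np.column_stack([fdr_correct(pmat[:, j], params.fdr_method)
                            for j in range(len(PAIRS))])
    for j, pair in enumerate(PAIRS):
        rec = records[pair]
        q = qmat[:, j]
        lo, hi = bands[pair][2], bands[pair][3]
        outside = (rec["fold_change"] < lo) | (rec["fold_change"] > hi)
        sig_pair = q < params.alpha
        direction = np.where(
            sig_pair & (rec["fold_change"] > 0), "up",
            np.where(sig_pair & (rec["fold_change"] < 0), "down", "none"),
        )
        rows.append(
            pd.DataFrame(
                {
                    "protein": matrix.proteins,
                    "pair": pair,
                    "fold_change": rec["fold_change"],
                    "F": rec["F"],
                    "p": rec["p"],
                    "q": q,
                    "outside_band": outside,
                    "direction": direction,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)

    p_combined = _simes(pmat)
    q_combined = fdr_correct(p_combined, params.fdr_method)
    if params.protein_rule == "simes":
        significant = q_combined < params.alpha
    else:
        significant = (qmat < params.alpha).any(axis=1)

    best_pair = np.full(n, -1)
    finite_any = np.isfinite(pmat).any(axis=1)
    best_pair[finite_any] = np.nanargmin(
        np.where(np.isfinite(pmat[finite_any]), pmat[finite_any], np.inf), axis=1
    )
    fold_all = np.column_stack([records[p]["fold_change"] for p in PAIRS])
    best_fold = np.where(
        best_pair >= 0, fold_all[np.arange(n), np.maximum(best_pair, 0)], np.nan
    )
    overall_dir = np.where(
        significant & (best_fold > 0), "up",
        np.where(significant & (best_fold < 0), "down", "none"),
    )
    proteins = pd.DataFrame(
        {
            "p_combined": p_combined,
            "q_combined": q_combined,
            "min_q": np.nanmin(np.where(np.isfinite(qmat), qmat, np.inf), axis=1),
            "significant": significant,
            "direction": overall_dir,
        },
        index=matrix.proteins,
    )
    proteins.loc[~np.isfinite(proteins["min_q"]), "min_q"] = np.nan
    return AgeVarianceResult(table=table, proteins=proteins, bands=bands, params=params)


def volcano_table(result: AgeVarianceResult) -> pd.DataFrame:
    """Per-(protein, pair) volcano export with significance tiers.

    Tiers are assigned on the FDR-corrected q: ``*`` < 0.05, ``**`` < 0.01,
    ``***`` < 0.001. Band bounds are repeated per row for plotting.
    """
    t = result.table.copy()
    with np.errstate(divide="ignore"):
        t["neg_log10_q"] = -np.log10(t["q"])
    tier = np.full(len(t), "", dtype=object)
    q = t["q"].to_numpy(float)
    tier[q < 0.05] = "*"
    tier[q < 0.01] = "**"
    tier[q < 0.001] = "***"
    t["tier"] = tier
    t["band_lower"] = t["pair"].map({p: b[2] for p, b in result.bands.items()})
    t["band_upper"] = t["pair"].map({p: b[3] for p, b in result.bands.items()})
    return t


def volcano_counts(result: AgeVarianceResult) -> pd.DataFrame:
    """Counts of significantly up / down proteins per SILAC pair."""
    t = result.table
    return (
        t[t["direction"].isin(["up", "down"])]
        .groupby(["pair", "direction"])
        .size()
        .unstack(fill_value=0)
        .reindex(list(PAIRS))
        .fillna(0)
        .astype(int)
    )
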