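"""Traditional MPRA analysis: activities, transcription shift, t/U tests, FDR.

The per-barcode *activity* in RNA sample r is

    activity(b, r) = ln( normRNA(b, r) / meanNormDNA(b) )

where counts are first depth-normalized (each sample column divided by its
depth factor = column sum / mean column sum of the same material, so depth
factors average 1 within DNA and within RNA) and barcodes with mean
normalized DNA count below a floor are removed.  A variant's *transcription
shift* is mean(alt activities) − mean(ref activities), pooling the three
transfections' (barcode, sample) observations as independent.  Two-sided
Welch t and Mann-Whitney U tests per variant are corrected with
Benjamini-Hochberg, separately within each test family.

Natural log is used throughout, so shifts are in nats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DegenerateSampleError, InsufficientDataError, MPRAError
from .io import BarcodeMap, CountTable

RESULT_COLUMNS = [
    "variant_id", "transcription_shift", "t_p", "t_q", "u_p", "u_q",
    "n_obs_ref", "n_obs_alt",
]


def depth_normalize(table: CountTable) -> CountTable:
    """Divide each sample column by its depth factor.

    depth_factor_s = column_sum_s / mean(column sums of samples with the
    same material), so within each material the factors average exactly 1
    and equal-depth samples are left untouched.
    """
    sums = table.counts.sum(axis=0).astype(float)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise DegenerateSampleError(f"zero-total sample column(s): {bad}")
    factors = pd.Series(index=sums.index, dtype=float)
    for material in ("DNA", "RNA"):
        cols = table.samples_of(material)
        if cols:
            factors[cols] = sums[cols] / sums[cols].mean()
    normalized = table.counts / factors
    samples = table.samples.copy()
    samples["depth_factor"] = factors
    return CountTable(normalized, samples, normalized=True)


def filter_low_dna(
    table: CountTable, min_norm_dna: float = 1.0
) -> tuple[CountTable, list[str]]:
    """Drop barcodes under-represented in the plasmid library.

    A barcode is removed iff its mean depth-normalized DNA count across the
    DNA samples is strictly below ``min_norm_dna``.
    """
    dna = table.dna_samples
    if not dna:
        raise ConfigurationError("no DNA sample in table")
    mean_dna = table.counts[dna].mean(axis=1)
    removed = list(table.counts.index[mean_dna < min_norm_dna])
    kept = CountTable(
        table.counts.loc[mean_dna >= min_norm_dna],
        table.samples.copy(),
        normalized=table.normalized,
    )
    return kept, removed


@dataclass
class ActivityTable:
    """Long-format activities: one row per retained (barcode, rna_sample)."""

    activities: pd.DataFrame  # columns: barcode, sample, variant_id, allele, activity
    n_dropped: int  # (barcode, sample) pairs with zero RNA, excluded from log


def compute_activities(table: CountTable, design: BarcodeMap) -> ActivityTable:
    """ln(normRNA / meanNormDNA) per (barcode, RNA sample).

    Pairs with zero RNA count are dropped (log undefined) and tallied;
    barcodes whose mean normalized DNA count is 0 contribute nothing.
    """
    dna, rna = table.dna_samples, table.rna_samples
    if not dna:
        raise ConfigurationError("no DNA sample in table")
    if not rna:
        raise ConfigurationError("no RNA sample in table")
    table.check_design(design)
    mean_dna = table.counts[dna].mean(axis=1)
    long = table.counts[rna].stack()
    long.index.names = ["barcode", "sample"]
    long = long.reset_index(name="norm_rna")
    long["mean_dna"] = mean_dna.loc[long["barcode"]].to_numpy()
    ok = (long["norm_rna"] > 0) & (long["mean_dna"] > 0)
    n_dropped = int((~ok).sum())
    kept = long[ok].copy()
    kept["activity"] = np.log(kept["norm_rna"] / kept["mean_dna"])
    info = design.table.loc[kept["barcode"]]
    kept["variant_id"] = info["variant_id"].to_numpy()
    kept["allele"] = info["allele"].to_numpy()
    cols = ["barcode", "sample", "variant_id", "allele", "activity"]
    return ActivityTable(kept[cols].reset_index(drop=True), n_dropped)


def _require_obs(ref: np.ndarray, alt: np.ndarray, min_obs: int = 2) -> None:
    if len(ref) < min_obs or len(alt) < min_obs:
        raise InsufficientDataError(
            f"need ≥{min_obs} activity observations per allele "
            f"(got ref={len(ref)}, alt={len(alt)})"
        )


def test_variant_t(ref, alt) -> tuple[float, float]:
    """Transcription shift and two-sided Welch t-test p-value.

    shift = mean(alt) − mean(ref).  If both groups are constant the t
    statistic is undefined; we report p = 1 for equal means (no evidence of
    shift) and p = 0 otherwise.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    _require_obs(ref, alt)
    shift = float(alt.mean() - ref.mean())
    if ref.var(ddof=1) == 0.0 and alt.var(ddof=1) == 0.0:
        return shift, 1.0 if shift == 0.0 else 0.0
    _, p = stats.ttest_ind(alt, ref, equal_var=False)
    return shift, float(p)


def _exact_u_pvalue(ref: np.ndarray, alt: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Enumerates every C(n1+n2, n1) split of the pooled values, computing U
    for each; handles ties exactly (it is a permutation test on U).
    p = min(1, 2·min(P(U ≤ u_obs), P(U ≥ u_obs))).
    """
    pooled = np.concatenate([alt, ref])
    n1 = len(alt)
    n = len(pooled)

    def u_stat(group1: np.ndarray, group2: np.ndarray) -> float:
        # number of (x in group1, y in group2) pairs with x > y, ties 1/2
        gt = (group1[:, None] > group2[None, :]).sum()
        eq = (group1[:, None] == group2[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(alt, ref)
    idx = np.arange(n)
    n_le = n_ge = total = 0
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return min(1.0, p)


def test_variant_u(ref, alt, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups have ≤ ``exact_max_n`` observations
    (valid under ties); tie-corrected normal approximation otherwise.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    _require_obs(ref, alt)
    if len(ref) <= exact_max_n and len(alt) <= exact_max_n:
        return _exact_u_pvalue(ref, alt)
    res = stats.mannwhitneyu(alt, ref, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input.

    q_(i) = min over j ≥ i of p_(j) · m / j (on the sorted scale), clipped
    to 1.  NAs are not allowed here: exclude them from the family first.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise MPRAError("p-values must lie in [0, 1] with no NA")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_frequentist(
    table: CountTable,
    design: BarcodeMap,
    min_norm_dna: float = 1.0,
    min_obs: int = 2,
) -> pd.DataFrame:
    """Full traditional pipeline: normalize → filter → activities → tests → BH.

    Returns one row per design variant with transcription shift, t/U
    p-values and BH q-values (each test family corrected across all
    variants with sufficient data; NAs excluded from the family and
    reported as NaN).
    """
    est = FrequentistMPRA(min_norm_dna=min_norm_dna, min_obs=min_obs)
    est.fit(table, design)
    return est.results_


class FrequentistMPRA(BaseEstimator):
    """Sklearn-style estimator wrapping the traditional MPRA analysis.

    Parameters
    ----------
    min_norm_dna : float
        Barcodes with mean depth-normalized DNA count below this are
        dropped before computing activities.
    min_obs : int
        Minimum activity observations per allele for a variant to enter
        the test families; variants below it are reported with NaN.

    Attributes (after ``fit``)
    --------------------------
    depth_factors_ : pd.Series        per-sample depth factors
    normalized_ : CountTable          depth-normalized counts
    removed_barcodes_ : list[str]     low-DNA barcodes removed
    activities_ : ActivityTable       per-(barcode, sample) activities
    results_ : pd.DataFrame           per-variant shift, p and q values
    """

    def __init__(self, min_norm_dna: float = 1.0, min_obs: int = 2):
        self.min_norm_dna = min_norm_dna
        self.min_obs = min_obs

    def fit(self, X: CountTable, y: BarcodeMap | None = None) -> "FrequentistMPRA":
        if y is None:
            raise ConfigurationError("fit requires the BarcodeMap as y")
        table, design = X, y
        table.check_design(design)
        normalized = depth_normalize(table)
        filtered, removed = filter_low_dna(normalized, self.min_norm_dna)
        acts = compute_activities(filtered, design)
        rows = []
        for vid, group in acts.activities.groupby("variant_id", sort=False):
            ref = group.loc[group["allele"] == "ref", "activity"].to_numpy()
            alt = group.loc[group["allele"] == "alt", "activity"].to_numpy()
            row = {
                "variant_id": vid,
                "n_obs_ref": len(ref),
                "n_obs_alt": len(alt),
                "transcription_shift": np.nan,
                "t_p": np.nan,
                "u_p": np.nan,
            }
            try:
                _require_obs(ref, alt, self.min_obs)
                row["transcription_shift"], row["t_p"] = test_variant_t(ref, alt)
                row["u_p"] = test_variant_u(ref, alt)
            except InsufficientDataError:
                pass
            rows.append(row)
        # variants absent from the activity table entirely (all barcodes filtered)
        seen = {r["variant_id"] for r in rows}
        for vid in design.variants:
            if vid not in seen:
                rows.append(
                    {
                        "variant_id": vid, "n_obs_ref": 0, "n_obs_alt": 0,
                        "transcription_shift": np.nan, "t_p": np.nan, "u_p": np.nan,
                    }
                )
        results = pd.DataFrame(rows)
        order = {v: i for i, v in enumerate(design.variants)}
        results = results.sort_values("variant_id", key=lambda s: s.map(order))
        results = results.reset_index(drop=True)
        for test in ("t", "u"):
            pcol, qcol = f"{test}_p", f"{test}_q"
            results[qcol] = np.nan
            ok = results[pcol].notna()
            if ok.any():
                results.loc[ok, qcol] = bh_fdr(results.loc[ok, pcol].to_numpy())
        self.depth_factors_ = normalized.samples["depth_factor"].copy()
        self.normalized_ = normalized
        self.removed_barcodes_ = removed
        self.activities_ = acts
        self.results_ = results[RESULT_COLUMNS]
        return self

    def fit_predict(self, X: CountTable, y: BarcodeMap) -> pd.DataFrame:
        return self.fit(X, y).results_
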