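"""Quality-control summaries: sample correlations and barcode representation.

Counts are log1p-transformed before correlating (raw barcode counts are
heavy-tailed, so a handful of jackpot barcodes would otherwise dominate a
Pearson coefficient); the transform and the method are configurable.
In a healthy experiment the two plasmid samples correlate near 1 while
plasmid-cDNA pairs are expectedly lower — cDNA counts pass through
transfection and transcription and carry extra biological noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSampleError
from .frequentist import depth_normalize
from .io import BarcodeMap, CountTable


def sample_correlations(
    table: CountTable, method: str = "pearson", log_transform: bool = True
) -> pd.DataFrame:
    """Pairwise sample correlation of ln(count+1) across barcodes.

    Constant columns have undefined correlation: their off-diagonal entries
    are NaN (never coerced to 0); the diagonal is 1 by convention.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    if table.counts.shape[1] < 2:
        raise ConfigurationError("need ≥2 samples for a correlation matrix")
    data = np.log1p(table.counts) if log_transform else table.counts.astype(float)
    corr = data.corr(method=method)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def representation_summary(
    table: CountTable, design: BarcodeMap, n_bins: int = 20
) -> dict:
    """Designed-barcode representation per sample plus a count histogram.

    Returns per-sample fractions of designed barcodes observed (≥1 count),
    and a histogram of mean depth-normalized DNA counts (the quantity the
    low-representation filter thresholds).
    """
    observed = {}
    designed = design.barcodes
    present = designed.intersection(table.barcodes)
    for sid in table.counts.columns:
        col = table.counts.loc[present, sid]
        observed[sid] = float((col > 0).sum() / len(designed)) if len(designed) else 0.0
    hist = {}
    try:
        norm = table if table.normalized else depth_normalize(table)
    except DegenerateSampleError:
        norm = None  # empty sample column: representation is still reported
    if norm is not None and norm.dna_samples:
        mean_dna = norm.counts[norm.dna_samples].mean(axis=1).to_numpy()
        counts, edges = np.histogram(mean_dna, bins=n_bins)
        hist = {"bin_edges": edges.tolist(), "counts": counts.tolist()}
    return {
        "fraction_observed": observed,
        "dna_mean_histogram": hist,
        "n_designed": int(len(designed)),
    }


@dataclass
class QCReport:
    """Serializable QC bundle; fractions lie in [0,1], correlation symmetric."""

    correlations: pd.DataFrame
    fraction_observed: dict
    dna_mean_histogram: dict
    sample_tallies: pd.DataFrame
    n_designed: int
    n_dropped_activities: int | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "correlations": {
                "index": list(self.correlations.index),
                "values": self.correlations.to_numpy().tolist(),
            },
            "fraction_observed": self.fraction_observed,
            "dna_mean_histogram": self.dna_mean_histogram,
            "sample_tallies": self.sample_tallies.reset_index().to_dict(orient="list"),
            "n_designed": self.n_designed,
            "n_dropped_activities": self.n_dropped_activities,
            "extra": self.extra,
        }
        return json.dumps(payload, indent=2, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "QCReport":
        d = json.loads(text)
        corr = pd.DataFrame(
            d["correlations"]["values"],
            index=d["correlations"]["index"],
            columns=d["correlations"]["index"],
        )
        tallies = pd.DataFrame(d["sample_tallies"]).set_index("sample_id")
        return cls(
            correlations=corr,
            fraction_observed=d["fraction_observed"],
            dna_mean_histogram=d["dna_mean_histogram"],
            sample_tallies=tallies,
            n_designed=d["n_designed"],
            n_dropped_activities=d["n_dropped_activities"],
            extra=d.get("extra", {}),
        )


def qc_report(
    table: CountTable,
    design: BarcodeMap,
    method: str = "pearson",
    n_dropped_activities: int | None = None,
) -> QCReport:
    rep = representation_summary(table, design)
    tally_cols = [c for c in ("total_reads", "assigned", "unmatched", "low_quality")
                  if c in table.samples.columns]
    return QCReport(
        correlations=sample_correlations(table, method=method),
        fraction_observed=rep["fraction_observed"],
        dna_mean_histogram=rep["dna_mean_histogram"],
        sample_tallies=table.samples[["material"] + tally_cols].copy(),
        n_designed=rep["n_designed"],
        n_dropped_activities=n_dropped_activities,
    )
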