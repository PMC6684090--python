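"""Barcode counting and count-table plumbing.

Demultiplexing is exact-match only: the barcode set is designed with a
minimum pairwise Hamming distance of 2, so a single sequencing error cannot
convert one designed barcode into another, and mismatch rescue is
unnecessary.  A read is counted iff the substring at the configured locator
equals a designed barcode AND every base of that substring has Phred
quality strictly greater than ``min_phred`` (default 30 — a Q30 base
fails, matching a strict "Q>30 at every base" rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import FastqParseError, SchemaError

MATERIALS = ("DNA", "RNA")

SAMPLE_COLUMNS = ["material", "total_reads", "assigned", "unmatched", "low_quality", "depth_factor"]


@dataclass
class SampleInfo:
    """Per-sample metadata; ``depth_factor`` is filled by depth normalization."""

    sample_id: str
    material: str
    total_reads: int = 0
    assigned: int = 0
    unmatched: int = 0
    low_quality: int = 0
    depth_factor: float = float("nan")

    def __post_init__(self):
        if self.material not in MATERIALS:
            raise SchemaError(f"material must be DNA or RNA, got {self.material!r}")


class BarcodeMap:
    """Barcode → (variant_id, allele) lookup defining the assay design."""

    def __init__(self, table: pd.DataFrame):
        required = {"variant_id", "allele"}
        if not required.issubset(table.columns):
            raise SchemaError(f"barcode map needs columns {sorted(required)}")
        if table.index.has_duplicates:
            dupes = table.index[table.index.duplicated()].unique().tolist()[:3]
            raise SchemaError(f"duplicate barcodes in map: {dupes}")
        bad = set(table["allele"]) - {"ref", "alt"}
        if bad:
            raise SchemaError(f"allele labels must be ref/alt, found {sorted(bad)}")
        self.table = table

    @property
    def barcodes(self) -> pd.Index:
        return self.table.index

    @property
    def variants(self) -> list[str]:
        return list(dict.fromkeys(self.table["variant_id"]))

    @property
    def barcode_length(self) -> int:
        return len(self.table.index[0])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.table.index

    def swap_alleles(self) -> "BarcodeMap":
        """Relabel ref↔alt (used for symmetry checks)."""
        swapped = self.table.copy()
        swapped["allele"] = swapped["allele"].map({"ref": "alt", "alt": "ref"})
        return BarcodeMap(swapped)

    @classmethod
    def from_designs(cls, designs) -> "BarcodeMap":
        rows = [
            (bc, d.variant_id, d.allele_label)
            for d in designs
            for bc in d.barcodes
        ]
        df = pd.DataFrame(rows, columns=["barcode", "variant_id", "allele"])
        return cls(df.set_index("barcode"))

    @classmethod
    def read_tsv(cls, path) -> "BarcodeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "barcode" not in df.columns:
            raise SchemaError("barcode map TSV needs a 'barcode' column")
        return cls(df.set_index("barcode"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="barcode")


class CountTable:
    """Barcode × sample counts plus per-sample metadata.

    ``counts``: DataFrame, index = barcodes, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with at least a ``material``
    column.  Raw tables hold non-negative integers; normalized tables
    (``normalized=True``) hold non-negative reals.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame, normalized: bool = False):
        if list(counts.columns) != list(samples.index):
            raise SchemaError("count columns and sample sheet rows disagree")
        if "material" not in samples.columns:
            raise SchemaError("sample sheet needs a 'material' column")
        bad_mat = set(samples["material"]) - set(MATERIALS)
        if bad_mat:
            raise SchemaError(f"unknown materials {sorted(bad_mat)}")
        values = counts.to_numpy()
        if values.size and np.any(values < 0):
            raise SchemaError("counts must be non-negative")
        if not normalized:
            if values.size and not np.allclose(values, np.round(values)):
                raise SchemaError("raw counts must be integers")
            counts = counts.astype(np.int64)
        counts = counts.rename_axis(index="barcode", columns=None)
        samples = samples.rename_axis(index="sample_id")
        self.counts = counts
        self.samples = samples
        self.normalized = normalized

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, material: str) -> list[str]:
        return list(self.samples.index[self.samples["material"] == material])

    @property
    def dna_samples(self) -> list[str]:
        return self.samples_of("DNA")

    @property
    def rna_samples(self) -> list[str]:
        return self.samples_of("RNA")

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.samples.copy(), self.normalized)

    def check_design(self, design: BarcodeMap) -> None:
        missing = self.counts.index.difference(design.barcodes)
        if len(missing):
            raise SchemaError(
                f"{len(missing)} barcodes absent from the design map "
                f"(e.g. {missing[:3].tolist()})"
            )


def _phred_from_string(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33


@dataclass
class ExtractionTally:
    """Bookkeeping for one FASTQ: assigned + unmatched + low_quality = total."""

    total: int = 0
    assigned: int = 0
    unmatched: int = 0
    low_quality: int = 0

    def check(self) -> None:
        assert self.assigned + self.unmatched + self.low_quality == self.total


def extract_barcodes(
    fastq_path,
    design: BarcodeMap,
    offset: int = 0,
    length: int | None = None,
    min_phred: int = 30,
) -> tuple[pd.Series, ExtractionTally]:
    """Count designed barcodes in one FASTQ(.gz) file.

    Returns a counts Series over all designed barcodes (zeros included) and
    the assigned/unmatched/low-quality tallies.  Order-independent: the
    result is a pure function of the read multiset.
    """
    if length is None:
        length = design.barcode_length
    if length != design.barcode_length:
        raise SchemaError(
            f"locator length {length} != design barcode length {design.barcode_length}"
        )
    lookup = set(design.barcodes)
    raw: dict[str, int] = {}
    tally = ExtractionTally()
    end = offset + length
    try:
        with pysam.FastxFile(str(fastq_path)) as fh:
            for i, entry in enumerate(fh):
                if entry.sequence is None or entry.quality is None:
                    raise FastqParseError(f"record {i} lacks sequence or quality", i)
                tally.total += 1
                bc = entry.sequence[offset:end].upper()
                if len(bc) < length or bc not in lookup:
                    tally.unmatched += 1
                    continue
                quals = _phred_from_string(entry.quality[offset:end])
                if np.any(quals <= min_phred):  # strict: Q == min_phred fails
                    tally.low_quality += 1
                    continue
                tally.assigned += 1
                raw[bc] = raw.get(bc, 0) + 1
    except FastqParseError:
        raise
    except (OSError, ValueError) as exc:
        raise FastqParseError(f"malformed FASTQ {fastq_path}: {exc}", tally.total) from exc
    tally.check()
    counts = pd.Series(0, index=design.barcodes, dtype=np.int64)
    if raw:
        found = pd.Series(raw)
        counts.loc[found.index] = found
    return counts, tally


def count_samples(
    sample_sheet: pd.DataFrame,
    design: BarcodeMap,
    offset: int = 0,
    min_phred: int = 30,
    fastq_root=None,
) -> CountTable:
    """Run extraction for every row of a sample sheet (sample_id, material, fastq)."""
    required = {"sample_id", "material", "fastq"}
    if not required.issubset(sample_sheet.columns):
        raise SchemaError(f"sample sheet needs columns {sorted(required)}")
    columns = {}
    meta_rows = []
    for row in sample_sheet.itertuples(index=False):
        path = Path(row.fastq)
        if fastq_root is not None and not path.is_absolute():
            path = Path(fastq_root) / path
        counts, tally = extract_barcodes(path, design, offset=offset, min_phred=min_phred)
        columns[row.sample_id] = counts
        meta_rows.append(
            {
                "sample_id": row.sample_id,
                "material": row.material,
                "total_reads": tally.total,
                "assigned": tally.assigned,
                "unmatched": tally.unmatched,
                "low_quality": tally.low_quality,
                "depth_factor": np.nan,
            }
        )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountTable(pd.DataFrame(columns), samples)


def _samples_sidecar(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".samples.tsv")


def write_count_table(table: CountTable, path, samples_path=None) -> None:
    """Write counts TSV (+ sample-metadata sidecar TSV for round-tripping)."""
    table.counts.to_csv(path, sep="\t", index_label="barcode")
    if samples_path is None:
        samples_path = _samples_sidecar(path)
    table.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_count_table(
    path, samples_path=None, design: BarcodeMap | None = None, normalized: bool = False
) -> CountTable:
    """Read a counts TSV; metadata comes from the sidecar written alongside.

    If ``design`` is given every barcode row must exist in the map.
    Negative or (for raw tables) non-integer cells raise :class:`SchemaError`.
    """
    counts = pd.read_csv(path, sep="\t", index_col="barcode")
    if counts.isna().to_numpy().any():
        raise SchemaError(f"missing values in count table {path}")
    if samples_path is None:
        samples_path = _samples_sidecar(path)
    samples_path = Path(samples_path)
    if samples_path.exists():
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    else:
        raise SchemaError(f"sample metadata sidecar {samples_path} not found")
    table = CountTable(counts, samples, normalized=normalized)
    if design is not None:
        table.check_design(design)
    return table
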