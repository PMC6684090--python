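"""Reporter-library design: restriction screening, barcodes, oligo assembly.

An MPRA oligo places a 150 bp genomic fragment carrying one allele of a
variant upstream of a KpnI/XbaI linker (where a minimal-promoter/luciferase
cassette is later inserted) followed by a transcribed, inert 10 bp barcode;
amplification primer arms flank the whole construct and contribute the SfiI
cloning sites.  Because SfiI, KpnI and XbaI are used during cloning, any
variant whose genomic context contains one of their recognition motifs must
be discarded, and barcodes must not create such motifs either on their own
or across the junctions with their flanking sequence.

All three default recognition motifs are palindromic as IUPAC patterns
(their reverse complement equals the pattern itself), so scanning a single
strand finds every site on either strand.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import SeqRecord, write as seqio_write

from .errors import CapacityError, DesignError, InvalidSequenceError, SchemaError

#: Restriction motifs screened during library construction (IUPAC).
DEFAULT_MOTIFS: dict[str, str] = {
    "SfiI": "GGCCNNNNNGGCC",
    "KpnI": "GGTACC",
    "XbaI": "TCTAGA",
}

#: Amplification primer arms; the forward arm carries an SfiI half-site.
DEFAULT_ARM_5 = "TGCTAAGGCCTAACTGGCCAG"
DEFAULT_ARM_3 = "CTCGGCGGCCAAGTATTCAT"

#: KpnI site followed by XbaI site: the cassette-insertion linker placed
#: between the genomic context and the barcode.
DEFAULT_LINKER = "GGTACCTCTAGA"

CONTEXT_LENGTH = 150
BARCODE_LENGTH = 10

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_DNA_RE = re.compile(r"^[ACGT]+$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_to_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into a lookahead regex finding overlapping hits."""
    try:
        body = "".join(_IUPAC[c] for c in motif.upper())
    except KeyError as exc:
        raise InvalidSequenceError(f"invalid IUPAC code {exc.args[0]!r} in motif {motif!r}")
    return re.compile(f"(?={body})")


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not seq or not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT")) if seq else []
        raise InvalidSequenceError(
            f"{what} must be non-empty uppercase ACGT"
            + (f"; found {bad}" if bad else "")
        )


def screen_restriction_sites(
    seq: str, motifs: dict[str, str] | None = None
) -> list[tuple[str, int]]:
    """Find every occurrence of each restriction motif in ``seq``.

    Returns ``(motif_name, offset)`` pairs, 0-based, sorted by offset then
    name, including overlapping occurrences.  Only the forward strand is
    scanned: the default SfiI/KpnI/XbaI patterns are their own reverse
    complements, so one-strand scanning already covers both strands.
    """
    _check_dna(seq)
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    hits: list[tuple[str, int]] = []
    for name, motif in motifs.items():
        pattern = iupac_to_regex(motif)
        hits.extend((name, m.start()) for m in pattern.finditer(seq))
    return sorted(hits, key=lambda h: (h[1], h[0]))


@dataclass(frozen=True)
class VariantSpec:
    """One allele of a variant with its genomic context.

    ``context_sequence`` is the 150 bp fragment, variant-centred, stored on
    the + strand of the design (0-based, half-open coordinates throughout).
    """

    variant_id: str
    allele_label: str  # "ref" or "alt"
    context_sequence: str
    source_note: str = ""

    def __post_init__(self):
        if self.allele_label not in ("ref", "alt"):
            raise DesignError(
                f"allele_label must be 'ref' or 'alt', got {self.allele_label!r}"
            )
        _check_dna(self.context_sequence, f"context of {self.variant_id}/{self.allele_label}")
        if len(self.context_sequence) != CONTEXT_LENGTH:
            raise DesignError(
                f"context of {self.variant_id}/{self.allele_label} has length "
                f"{len(self.context_sequence)}, expected {CONTEXT_LENGTH}"
            )


@dataclass
class OligoDesign:
    """All assembled oligos for one allele of one variant."""

    variant_id: str
    allele_label: str
    context_sequence: str
    barcodes: list[str]
    arm_5: str = DEFAULT_ARM_5
    arm_3: str = DEFAULT_ARM_3
    linker: str = DEFAULT_LINKER
    full_oligos: list[str] = field(default_factory=list)

    @property
    def context_offset(self) -> int:
        return len(self.arm_5)

    def barcode_offset(self) -> int:
        return len(self.arm_5) + len(self.context_sequence) + len(self.linker)


def _pair_specs(specs: list[VariantSpec]) -> dict[str, dict[str, VariantSpec]]:
    by_variant: dict[str, dict[str, VariantSpec]] = {}
    for spec in specs:
        alleles = by_variant.setdefault(spec.variant_id, {})
        if spec.allele_label in alleles:
            raise DesignError(
                f"duplicate allele {spec.allele_label!r} for variant {spec.variant_id}"
            )
        alleles[spec.allele_label] = spec
    for vid, alleles in by_variant.items():
        if set(alleles) != {"ref", "alt"}:
            raise DesignError(f"variant {vid} is unpaired (has {sorted(alleles)})")
        if alleles["ref"].context_sequence == alleles["alt"].context_sequence:
            raise DesignError(f"variant {vid}: ref and alt contexts are identical")
    return by_variant


def filter_variants(
    specs: list[VariantSpec], motifs: dict[str, str] | None = None
) -> tuple[list[VariantSpec], list[tuple[VariantSpec, str]]]:
    """Discard variants whose context (either allele) contains a screened motif.

    Returns ``(kept, discarded)`` where ``discarded`` pairs each dropped
    allele spec with a reason naming the motif and the allele that carries
    it.  Both alleles of a discarded variant are dropped.  Idempotent: the
    kept set passes a second application unchanged.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    by_variant = _pair_specs(specs)
    kept: list[VariantSpec] = []
    discarded: list[tuple[VariantSpec, str]] = []
    for spec in specs:  # preserve input order
        alleles = by_variant[spec.variant_id]
        reasons = []
        for label in ("ref", "alt"):
            for name, off in screen_restriction_sites(
                alleles[label].context_sequence, motifs
            ):
                reasons.append(f"{name} site at offset {off} in {label} context")
        if reasons:
            discarded.append((spec, "; ".join(reasons)))
        else:
            kept.append(spec)
    return kept, discarded


def _max_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def generate_barcodes(
    n: int,
    length: int = BARCODE_LENGTH,
    seed: int | None = None,
    motifs: dict[str, str] | None = None,
    max_homopolymer: int = 3,
    min_hamming: int = 2,
    flanks: tuple[str, str] | None = None,
    max_attempts_factor: int = 2000,
) -> list[str]:
    """Sample ``n`` unique barcodes satisfying the design constraints.

    Constraints: no screened restriction motif inside the barcode (or, when
    ``flanks`` is given, in ``left + barcode + right`` — covering junction
    artefacts at assembly time); no homopolymer run longer than
    ``max_homopolymer``; every pair at Hamming distance ≥ ``min_hamming``.
    Deterministic for a given seed.

    The pairwise-distance constraint is enforced without O(n²) comparisons:
    two length-L barcodes are within Hamming distance 1 iff they share one
    of the L single-position-wildcarded keys, so a set of seen keys suffices
    (only ``min_hamming`` ≤ 2 is supported, matching exact-match
    demultiplexing needs).
    """
    if min_hamming > 2:
        raise NotImplementedError("min_hamming > 2 is not supported")
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    if n > 4**length:
        raise CapacityError(f"cannot draw {n} unique barcodes of length {length}")
    named_patterns = {name: iupac_to_regex(m) for name, m in motifs.items()}
    left, right = flanks if flanks is not None else ("", "")

    def _motif_overlaps_barcode(flanked: str) -> bool:
        # hits entirely inside a flank are part of the designed construct
        lo, hi = len(left), len(left) + length
        for name, pattern in named_patterns.items():
            mlen = len(motifs[name])
            for m in pattern.finditer(flanked):
                if m.start() < hi and m.start() + mlen > lo:
                    return True
        return False

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    barcodes: list[str] = []
    masked_keys: set[str] = set()
    attempts = 0
    max_attempts = max(1000, max_attempts_factor * n)
    while len(barcodes) < n:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"could not find {n} barcodes of length {length} satisfying the "
                f"constraints after {max_attempts} draws (got {len(barcodes)})"
            )
        bc = "".join(bases[rng.integers(0, 4, size=length)])
        if _max_homopolymer(bc) > max_homopolymer:
            continue
        if _motif_overlaps_barcode(left + bc + right):
            continue
        keys = [bc[:i] + "." + bc[i + 1 :] for i in range(length)]
        if min_hamming >= 2 and any(k in masked_keys for k in keys):
            continue
        if min_hamming < 2 and bc in barcodes:
            continue
        barcodes.append(bc)
        masked_keys.update(keys)
    return barcodes


def assemble_oligos(
    specs: list[VariantSpec],
    n_barcodes: int = 40,
    seed: int | None = None,
    motifs: dict[str, str] | None = None,
    arm_5: str = DEFAULT_ARM_5,
    arm_3: str = DEFAULT_ARM_3,
    linker: str = DEFAULT_LINKER,
) -> list[OligoDesign]:
    """Assign ``n_barcodes`` unique barcodes per allele and build full oligos.

    Full oligo = arm_5 + context + linker + barcode + arm_3.  Barcodes are
    generated with junction flanks so no screened motif occurs outside the
    designed linker/arm positions; this is re-verified on every assembled
    oligo and violations raise :class:`DesignError`.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    by_variant = _pair_specs(specs)
    # junction context around the barcode: linker tail on the left, arm on the right
    flanks = (linker[-(BARCODE_LENGTH + 2) :], arm_3[: BARCODE_LENGTH + 2])
    ordered = [by_variant[v][a] for v in by_variant for a in ("ref", "alt")]
    pool = generate_barcodes(
        n_barcodes * len(ordered), seed=seed, motifs=motifs, flanks=flanks
    )
    designed_hits = _designed_positions(arm_5, arm_3, linker, motifs)
    designs: list[OligoDesign] = []
    for i, spec in enumerate(ordered):
        bcs = pool[i * n_barcodes : (i + 1) * n_barcodes]
        design = OligoDesign(
            variant_id=spec.variant_id,
            allele_label=spec.allele_label,
            context_sequence=spec.context_sequence,
            barcodes=bcs,
            arm_5=arm_5,
            arm_3=arm_3,
            linker=linker,
        )
        for bc in bcs:
            oligo = arm_5 + spec.context_sequence + linker + bc + arm_3
            _validate_oligo(oligo, design, bc, motifs, designed_hits)
            design.full_oligos.append(oligo)
        designs.append(design)
    return designs


def _designed_positions(
    arm_5: str, arm_3: str, linker: str, motifs: dict[str, str]
) -> set[tuple[str, str]]:
    """Motif hits that are part of the construct design (arms and linker)."""
    designed = set()
    for region, seq in (("arm_5", arm_5), ("arm_3", arm_3), ("linker", linker)):
        for name, off in screen_restriction_sites(seq, motifs):
            designed.add((region, name, off))
    return designed


def _validate_oligo(oligo, design, barcode, motifs, designed_hits) -> None:
    ctx_start = design.context_offset
    ctx_end = ctx_start + len(design.context_sequence)
    link_end = ctx_end + len(design.linker)
    bc_end = link_end + len(barcode)
    regions = {
        "arm_5": (0, ctx_start),
        "linker": (ctx_end, link_end),
        "arm_3": (bc_end, len(oligo)),
    }
    for name, off in screen_restriction_sites(oligo, motifs):
        end = off + len(motifs[name])
        ok = False
        for region, (lo, hi) in regions.items():
            if lo <= off and end <= hi and (region, name, off - lo) in designed_hits:
                ok = True
                break
        if not ok:
            raise DesignError(
                f"{design.variant_id}/{design.allele_label}: undesigned {name} "
                f"site at oligo offset {off} (barcode {barcode})"
            )
    if oligo.count(barcode) != 1 or oligo.count(design.context_sequence) != 1:
        raise DesignError(
            f"{design.variant_id}/{design.allele_label}: barcode or context "
            "does not occur exactly once in the assembled oligo"
        )


def read_variant_table(path) -> list[VariantSpec]:
    """Read a variant design TSV (variant_id, allele, context_sequence[, note])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "allele", "context_sequence"}
    if not required.issubset(df.columns):
        raise SchemaError(f"variant table needs columns {sorted(required)}")
    return [
        VariantSpec(
            variant_id=row.variant_id,
            allele_label=row.allele,
            context_sequence=row.context_sequence,
            source_note=getattr(row, "note", "") or "",
        )
        for row in df.itertuples(index=False)
    ]


def write_oligo_fasta(designs: list[OligoDesign], path) -> None:
    """Write every assembled oligo as FASTA (id = variant|allele|barcode)."""
    records = [
        SeqRecord(
            Seq(oligo),
            id=f"{d.variant_id}|{d.allele_label}|{bc}",
            description="",
        )
        for d in designs
        for bc, oligo in zip(d.barcodes, d.full_oligos)
    ]
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")
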