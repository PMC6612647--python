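"""CpG-related SNP (CGS) annotation.

A CGS is a biallelic SNV one of whose alleles creates, and the other
disrupts, a CpG dinucleotide in its reference sequence context.  Because a
substituted base at position ``pos`` can participate in at most the two
dinucleotides ``(pos-1, pos)`` and ``(pos, pos+1)``, each allele's CpG count
lies in {0, 1, 2}.  The allele with the larger count is the CpG-creating
*effect allele*; the other allele is treated as the reference level of the
CpG-dosage exposure downstream.

CpG is palindromic across strands (its reverse complement is itself), so
classifying on the forward strand is complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(ValueError):
    """Raised for inconsistent or malformed variant/context input."""


@dataclass(frozen=True)
class ReferenceContext:
    """Immediate sequence context of a variant site.

    ``left_base``/``right_base`` are the reference nucleotides at pos-1 and
    pos+1; ``None`` marks a flank that does not exist (sequence edge), which
    is distinct from an ``'N'`` base.
    """

    chrom: str
    pos: int  # 1-based
    left_base: Optional[str]
    right_base: Optional[str]

    def __post_init__(self) -> None:
        for base in (self.left_base, self.right_base):
            if base is not None and base not in VALID_BASES | {"N"}:
                raise AnnotationError(f"invalid context base {base!r} at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with imputation metadata."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref_allele: str
    alt_allele: str
    imputation_r2: float = 1.0
    maf: float = 0.0
    cohorts_present: int = 1

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise AnnotationError(f"variant {self.id}: ref equals alt ({self.ref_allele})")
        if not (0.0 <= self.maf <= 0.5):
            raise AnnotationError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class CGSAnnotation:
    """Classification of one variant as CGS or non-CGS."""

    variant: VariantRecord
    cpg_count_ref: int
    cpg_count_alt: int
    is_cgs: bool
    effect_allele: Optional[str]  # CpG-creating allele; None when not CGS
    delta: int  # |count difference|; >= 1 iff is_cgs
    context_incomplete: bool = False


def _cpg_count(left: Optional[str], allele: str, right: Optional[str]) -> int:
    """Number of CpG dinucleotides overlapping the site when ``allele`` is present."""
    count = 0
    if left == "C" and allele == "G":
        count += 1
    if allele == "C" and right == "G":
        count += 1
    return count


def _needs_flank(left: Optional[str], right: Optional[str], ref: str, alt: str) -> bool:
    """True when an unknown flank could change the classification.

    The left flank matters only if some allele is G; the right flank only
    if some allele is C.  An 'N' on a side that matters makes CpG formation
    undeterminable.  A missing flank (sequence edge, ``None``) is different:
    the dinucleotide simply does not exist, so that side contributes a
    definitive count of zero.
    """
    return (left == "N" and "G" in (ref, alt)) or (right == "N" and "C" in (ref, alt))


def classify_variant(context: ReferenceContext, variant: VariantRecord) -> CGSAnnotation:
    """Classify one biallelic SNV against its reference context.

    Each allele is substituted at the variant position and the CpG
    dinucleotides overlapping the position are counted.  ``is_cgs`` is true
    iff the two counts differ; the effect allele is the one with the larger
    count.  Sites whose classification hinges on an unknown flank are
    returned non-CGS with ``context_incomplete`` set.
    """
    if (context.chrom, context.pos) != (variant.chrom, variant.pos):
        raise AnnotationError(
            f"context {context.chrom}:{context.pos} does not match "
            f"variant {variant.chrom}:{variant.pos} ({variant.id})"
        )
    for allele in (variant.ref_allele, variant.alt_allele):
        if allele not in VALID_BASES:
            raise AnnotationError(f"variant {variant.id}: non-ACGT allele {allele!r}")

    if _needs_flank(context.left_base, context.right_base, variant.ref_allele, variant.alt_allele):
        return CGSAnnotation(
            variant=variant, cpg_count_ref=0, cpg_count_alt=0,
            is_cgs=False, effect_allele=None, delta=0, context_incomplete=True,
        )

    n_ref = _cpg_count(context.left_base, variant.ref_allele, context.right_base)
    n_alt = _cpg_count(context.left_base, variant.alt_allele, context.right_base)
    is_cgs = n_ref != n_alt
    effect = None
    if is_cgs:
        effect = variant.ref_allele if n_ref > n_alt else variant.alt_allele
    return CGSAnnotation(
        variant=variant, cpg_count_ref=n_ref, cpg_count_alt=n_alt,
        is_cgs=is_cgs, effect_allele=effect, delta=abs(n_ref - n_alt),
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotationSummary:
    n_cgs: int = 0
    n_non_cgs: int = 0
    n_skipped: int = 0


def annotate_variants(
    fasta_path: str,
    vcf_path: str,
    summary: Optional[AnnotationSummary] = None,
) -> Iterator[CGSAnnotation]:
    """Stream CGS annotations for the biallelic SNVs of a VCF.

    Indels and multi-allelic records are skipped (counted in ``summary``).
    A VCF chromosome absent from the FASTA is a hard error.
    """
    from cyvcf2 import VCF
    from pyfaidx import Fasta

    fasta = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    if summary is None:
        summary = AnnotationSummary()
    for rec in VCF(vcf_path):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            summary.n_skipped += 1
            continue
        chrom = rec.CHROM
        if chrom not in fasta:
            raise AnnotationError(f"chromosome {chrom!r} in VCF but not in FASTA {fasta_path}")
        seq = fasta[chrom]
        length = len(seq)
        pos = rec.POS  # 1-based
        left = seq[pos - 2] if pos >= 2 else None
        right = seq[pos] if pos < length else None
        try:
            r2 = float(rec.INFO.get("R2", 1.0))
        except (TypeError, ValueError):
            r2 = 1.0
        ncoh = int(rec.INFO.get("NCOH", 1) or 1)
        try:
            maf = float(rec.INFO.get("MAF", 0.0) or 0.0)
        except (TypeError, ValueError):
            maf = 0.0
        variant = VariantRecord(
            chrom=chrom, pos=pos, id=rec.ID or f"{chrom}:{pos}",
            ref_allele=rec.REF, alt_allele=rec.ALT[0],
            imputation_r2=r2, maf=min(maf, 0.5), cohorts_present=ncoh,
        )
        context = ReferenceContext(chrom=chrom, pos=pos, left_base=left, right_base=right)
        ann = classify_variant(context, variant)
        if ann.is_cgs:
            summary.n_cgs += 1
        else:
            summary.n_non_cgs += 1
        yield ann
    logger.info(
        "annotated variants: %d CGS, %d non-CGS, %d skipped (non-SNV)",
        summary.n_cgs, summary.n_non_cgs, summary.n_skipped,
    )


ANNOTATION_COLUMNS = [
    "chrom", "pos", "id", "ref", "alt", "is_cgs", "effect_allele", "delta", "r2", "maf",
]


def annotations_to_frame(annotations: Iterable[CGSAnnotation]):
    """Tabulate annotations with the standard TSV columns."""
    import pandas as pd

    rows = []
    for a in annotations:
        v = a.variant
        rows.append(
            (v.chrom, v.pos, v.id, v.ref_allele, v.alt_allele, a.is_cgs,
             a.effect_allele or ".", a.delta, v.imputation_r2, v.maf)
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations_tsv(annotations: Iterable[CGSAnnotation], path: str) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
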