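import warnings

import numpy as np
import pytest

from cgwas.annotation import CGSAnnotation, ReferenceContext, VariantRecord

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def brute_force_cpg_counts(left, ref, alt, right):
    """Independent oracle: substitute each allele into the 3-mer and count 'CG'."""
    counts = []
    for allele in (ref, alt):
        trimer = "".join(b if b is not None else "." for b in (left, allele, right))
        counts.append(sum(1 for i in range(len(trimer) - 1) if trimer[i:i + 2] == "CG"))
    return tuple(counts)


def make_variant(chrom="chr1", pos=100, vid="v1", ref="C", alt="T", r2=1.0,
                 maf=0.2, ncoh=1):
    return VariantRecord(chrom=chrom, pos=pos, id=vid, ref_allele=ref,
                         alt_allele=alt, imputation_r2=r2, maf=maf,
                         cohorts_present=ncoh)


def make_annotation(pos, vid, is_cgs=True, effect_is_alt=True, ref="C", alt="T",
                    r2=1.0, maf=0.2, ncoh=1, chrom="chr1"):
    """Construct a CGSAnnotation directly (for windowing/association tests)."""
    v = make_variant(chrom=chrom, pos=pos, vid=vid, ref=ref, alt=alt, r2=r2,
                     maf=maf, ncoh=ncoh)
    effect = alt if effect_is_alt else ref
    return CGSAnnotation(
        variant=v, cpg_count_ref=0 if effect_is_alt else 1,
        cpg_count_alt=1 if effect_is_alt else 0,
        is_cgs=is_cgs, effect_allele=effect if is_cgs else None,
        delta=1 if is_cgs else 0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
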