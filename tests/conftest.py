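import numpy as np
import pytest

from dosagescope.core_io import (
    CnvRecord,
    CnvType,
    GeneRecord,
    GenomeBuild,
    Interpretation,
)


@pytest.fixture
def toy_build():
    return GenomeBuild("toy", {"1": 1_000_000, "2": 800_000})


def make_cnv(start, end, cnv_type="gain", interpretation="benign",
             chrom="1", cid=None):
    return CnvRecord(
        id=cid or f"c_{chrom}_{start}_{end}_{cnv_type}",
        chromosome=chrom, start=start, end=end,
        cnv_type=CnvType(cnv_type), interpretation=Interpretation(interpretation),
    )


def make_gene(gid, start, end, chrom="1", **flags):
    hi = flags.pop("hi_score", None)
    expr = flags.pop("max_expression", None)
    ancestral = flags.pop("ancestral", True)
    strand = flags.pop("strand", "+")
    return GeneRecord(
        gene_id=gid, chromosome=chrom, start=start, end=end, strand=strand,
        flags=flags, hi_score=hi, max_expression=expr, ancestral=ancestral,
    )


def random_cnv_set(rng, n, build, interpretation="benign"):
    """Random valid CNVs on a build (respecting the 50 bp / 10% bounds)."""
    out = []
    chroms = list(build.chrom_lengths)
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = build.chrom_lengths[chrom]
        length = int(rng.integers(50, max(51, int(0.1 * L))))
        start = int(rng.integers(0, L - length + 1))
        out.append(
            make_cnv(start, start + length,
                     cnv_type="gain" if rng.random() < 0.5 else "loss",
                     interpretation=interpretation, chrom=chrom, cid=f"r{i}")
        )
    return out
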