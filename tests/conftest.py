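import numpy as np
import pandas as pd
import pytest

from mmclonetrack import exprscore, sigfit
from mmclonetrack.mutcat import MutationRecord


@pytest.fixture(scope="session")
def toy_ref():
    return sigfit.toy_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_mut(chrom="chr1", pos=100, ref="C", alt="T", context=None, **kw):
    kw.setdefault("patient_id", "P01")
    kw.setdefault("sample_id", "S1")
    kw.setdefault("alt_reads", 10)
    kw.setdefault("total_reads", 40)
    return MutationRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, context=context, **kw
    )


@pytest.fixture()
def tiny_tpm():
    """5 genes x 4 samples TPM matrix with hand-pickable values."""
    return pd.DataFrame(
        {
            "s1": [1.0, 8.0, 0.0, 3.0, 50.0],
            "s2": [2.0, 4.0, 1.0, 3.0, 10.0],
            "s3": [3.0, 2.0, 4.0, 3.0, 5.0],
            "s4": [4.0, 1.0, 9.0, 3.0, 1.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )


@pytest.fixture()
def small_vcf(tmp_path):
    """VCF with 3 SNVs and 1 indel, AD-style depths."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
chr1\t100\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:30,10
chr1\t200\t.\tG\tA\t.\tPASS\t.\tGT:AD\t0/1:20,20
chr1\t300\t.\tA\tAT\t.\tPASS\t.\tGT:AD\t0/1:25,5
chr1\t400\t.\tT\tG\t.\tPASS\t.\tGT:AD\t0/1:18,2
"""
    path = tmp_path / "muts.vcf"
    path.write_text(text)
    return path
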