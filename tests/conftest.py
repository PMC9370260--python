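import numpy as np
import pytest

from mrax.summary_io import HarmonizedInstrument, SummaryStat


def mk_stat(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3, p=None, n=50_000):
    return SummaryStat(
        snp_id=snp, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, eaf=eaf, pvalue=p, n=n,
    )


def mk_insts(bx, by, sx=None, sy=None):
    """Harmonized instruments from effect arrays (default tiny/unit SEs)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, dtype=float)
    sy = np.ones_like(bx) if sy is None else np.asarray(sy, dtype=float)
    return [
        HarmonizedInstrument(
            snp_id=f"rs{i + 1:03d}", beta_exp=float(bx[i]), se_exp=float(sx[i]),
            beta_out=float(by[i]), se_out=float(sy[i]),
        )
        for i in range(bx.size)
    ]


@pytest.fixture
def clean_ten_snp():
    """Ten strong instruments, common ratio 0.3 plus small noise, fixed seed."""
    rng = np.random.default_rng(42)
    bx = rng.uniform(0.05, 0.12, 10)
    sx = np.full(10, 0.005)
    sy = np.full(10, 0.02)
    by = 0.3 * bx + rng.normal(0, sy)
    return mk_insts(bx, by, sx, sy)
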