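import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from svharmony import SimConfig, simulate_bundle
from svharmony.model_io import GenotypeMatrix, SVRecord


@pytest.fixture(scope="session")
def small_bundle():
    """A modest two-study cohort with replicates, planted duplicates,
    fragmentation, and false positives."""
    cfg = SimConfig(seed=7, n_donors=60, n_twin_pairs=6, n_fib_ipsc_pairs=10)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def clean_bundle():
    """No jitter, no genotype error, no duplicates/fragments/FPs: every view
    reproduces the truth exactly."""
    cfg = SimConfig(
        seed=11, n_donors=40, n_twin_pairs=5, n_fib_ipsc_pairs=5,
        uniform_error=0.0, jitter_bound=0, fragmentation_prob=0.0,
        duplicate_prob=0.0, n_false_positives=0,
    )
    return simulate_bundle(cfg)


def make_record(site_id, chrom="chr1", start=1000, end=2000, svtype="DEL",
                caller="speedseq", quality=None, sv_len=None, flags=()):
    if svtype in ("BND", "INS", "ALU", "LINE1", "SVA"):
        end = start + 1
    return SVRecord(
        site_id=site_id, caller=caller, chrom=chrom, start=start, end=end,
        svtype=svtype, sv_len=sv_len if sv_len is not None else max(1, end - start),
        quality=dict(quality or {}), melt_flags=frozenset(flags),
    )


def make_matrix(site_ids, n_samples, gt=None, cn=None, ab=None, lq=None, seed=0):
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{j:03d}" for j in range(n_samples)]
    if gt is None:
        gt = rng.integers(0, 3, size=(len(site_ids), n_samples))
    return GenotypeMatrix(site_ids, sample_ids, gt=np.asarray(gt, dtype=np.int16),
                          cn=cn, ab=ab, lq=lq)
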