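import numpy as np
import pytest

from hrdscape.reference_io import ASCNSegment, GenomeBuild, load_genome_build
from hrdscape.scar_signatures import ScarParams


@pytest.fixture(scope="session")
def toy_genome():
    return load_genome_build("toy")


@pytest.fixture(scope="session")
def hg38_genome():
    return load_genome_build("hg38")


@pytest.fixture(scope="session")
def mini_genome():
    """3 x 100 bp genome: scar rules exercised at base-pair scale."""
    chroms = tuple((f"chr{i}", 100) for i in (1, 2, 3))
    cen = {c: (45, 55) for c, _ in chroms}
    bands = {
        c: (("p2", 1, 25), ("p1", 26, 50), ("q1", 51, 75), ("q2", 76, 100))
        for c, _ in chroms
    }
    return GenomeBuild("mini", chroms, cen, bands)


@pytest.fixture(scope="session")
def mini_params():
    """Scar thresholds scaled to the base-pair mini genome."""
    return ScarParams(
        loh_min_len=15, lst_min_segment=10, lst_smooth_len=3, tai_min_len=0
    )


def random_mini_profile(rng, sample="S1", gap_prob=0.15):
    """Random small ASCN profile on the mini genome, gaps allowed."""
    segs = []
    for chrom in ("chr1", "chr2", "chr3"):
        if rng.random() < 0.1:
            continue
        k = int(rng.integers(0, 8))
        cuts = np.sort(rng.choice(np.arange(2, 100), size=k, replace=False))
        bounds = [1, *cuts.tolist(), 101]
        for s, e in zip(bounds[:-1], bounds[1:]):
            if rng.random() < gap_prob:
                continue
            n_major = int(rng.integers(0, 4))
            n_minor = int(rng.integers(0, n_major + 1))
            segs.append(ASCNSegment(sample, chrom, s, e - 1, n_major, n_minor))
    return segs


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated bimodal cohort shared across tests."""
    from hrdscape.synthetic import simulate_cohort

    return simulate_cohort(30, 30, seed=42)
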