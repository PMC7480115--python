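import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scnalnc import synthetic as syn
from scnalnc.models import AMPLIFICATION, PlantedAlteration, SegmentSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    """Two 10-Mb chromosomes with coding, lncRNA, driver and pseudo genes."""
    return syn.make_genome(2, 10_000_000, 40, 20, 4, 5, seed=1)


@pytest.fixture(scope="session")
def planted_lnc(genome):
    """An amplification planted tightly over an isolated lncRNA (pad smaller
    than one marker bin), so the interval contains only that gene."""
    g = syn.pick_isolated_lncrna(genome)
    start, end = max(0, g.start - 5_000), g.end + 5_000
    return PlantedAlteration(g.chromosome, start, end, AMPLIFICATION, 0.10, 1.5, 0.1), g


@pytest.fixture(scope="session")
def planted_cohort(genome, planted_lnc):
    alt, _ = planted_lnc
    segments, carriers = syn.simulate_cohort(genome, [alt], seed=11)
    return segments, carriers, alt


def flat_segments(values_by_sample, chrom="chr1", length=1_000_000, labels=None):
    """SegmentSet with one constant segment per sample covering the chromosome."""
    rows = [(s, chrom, 0, length, v) for s, v in values_by_sample.items()]
    df = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "log2_ratio"])
    return SegmentSet(df, labels or {}).validate()
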