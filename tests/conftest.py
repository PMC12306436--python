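import pytest

from ivbench import SimConfig, simulate_reference, write_dataset


@pytest.fixture(scope="session")
def ref100():
    """A 100-interval reference set shared by read-only tests."""
    return simulate_reference(SimConfig(intvlnums=100, seed=7))


@pytest.fixture(scope="session")
def dataset100(ref100, tmp_path_factory):
    """A written 100-interval dataset directory (ref, queries, truth)."""
    d = tmp_path_factory.mktemp("ds") / "n100"
    write_dataset(ref100, d)
    return d


@pytest.fixture(scope="session")
def dataset10(tmp_path_factory):
    """A written 10-interval dataset directory (single chromosome)."""
    ref = simulate_reference(SimConfig(intvlnums=10, seed=3))
    d = tmp_path_factory.mktemp("ds10") / "n10"
    write_dataset(ref, d)
    return d


def brute_force_hits(intervals, probe):
    """Independent exhaustive-scan oracle: ids of intervals sharing >=1 base
    with the probe, in (chrom, start, end, id) order.  Kept free of the
    package's engine and predicate code on purpose."""
    hits = [
        iv
        for iv in intervals
        if iv.chrom == probe.chrom and max(iv.start, probe.start) < min(iv.end, probe.end)
    ]
    hits.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id))
    return [iv.id for iv in hits]
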