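import numpy as np
import pytest

from kbsites import KappaBSite, PeakRegion, ZScoreTable, classify_site


@pytest.fixture
def sentinel_table():
    """The two literature reference sites: one strong, one weak."""
    return ZScoreTable({"GGGAAATTCC": 14.0, "GGGAAGTTCC": 5.8}, source_label="sentinels")


def make_site(start, z, strand="+", kmer="GGGAAATTCC", mismatches=0):
    return KappaBSite(
        start=start,
        strand=strand,
        kmer=kmer,
        z_score=z,
        mismatches=mismatches,
        site_class=classify_site(z),
    )


def make_peak(region_id, chip_score, site_specs, length=1001, anchor_start=None):
    """Build a PeakRegion directly from (start, z) site specs.

    The anchor is the max-Z site (first such on ties) unless ``anchor_start``
    names it.
    """
    sites = [make_site(start, z) for start, z in site_specs]
    if anchor_start is None:
        anchor = max(sites, key=lambda s: s.z_score)
    else:
        anchor = next(s for s in sites if s.start == anchor_start)
    return PeakRegion(
        region_id=region_id,
        sequence="A" * length,
        anchor_offset=anchor.center,
        chip_score=chip_score,
        sites=sites,
    )


def random_table_and_sequence(rng, max_len=2000, max_entries=100):
    """A random scan instance: sequence with some table k-mers embedded."""
    from kbsites.simulate import gen_zscore_table

    n_entries = int(rng.integers(1, max_entries + 1))
    table = gen_zscore_table(n_entries, seed=int(rng.integers(2**31)))
    length = int(rng.integers(10, max_len + 1))
    seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    # embed a few table k-mers (possibly reverse-complemented) to make hits likely
    kmers = list(table.entries)
    for _ in range(int(rng.integers(0, 6))):
        if length < 10:
            break
        start = int(rng.integers(0, length - 9))
        kmer = kmers[int(rng.integers(len(kmers)))]
        if rng.integers(2):
            from kbsites import reverse_complement

            kmer = reverse_complement(kmer)
        seq = seq[:start] + kmer + seq[start + 10 :]
    return seq, table
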