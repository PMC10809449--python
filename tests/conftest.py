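import pytest

from oran import synthetic_fixtures as fx


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_gtf(path, rows):
    """rows: (chrom, feature, start1, end1, strand, frame, attrs)"""
    with open(path, "w") as fh:
        for chrom, feature, s, e, strand, frame, attrs in rows:
            fh.write("\t".join([chrom, "test", feature, str(s), str(e),
                                ".", strand, str(frame), attrs]) + "\n")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One seed-fixed fixture bundle shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = fx.write_fixture(fx.FixtureSpec(seed=0), outdir)
    return paths


@pytest.fixture(scope="session")
def default_reference():
    return fx.make_reference(fx.FixtureSpec(seed=0))
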