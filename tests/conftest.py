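import pytest

from trophicpos import IsotopeSample, packaged_baselines


def make_sample(d15n, species="Acanthurus synthetica", guild="herbivore-detritivore",
                season="pooled", sample_id=None):
    return IsotopeSample(
        sample_id=sample_id or f"{species}|{season}|{d15n}",
        species=species,
        guild=guild,
        season=season,
        d15N=d15n,
    )


@pytest.fixture
def pooled_baselines():
    return {b.name: b for b in packaged_baselines("pooled")}


@pytest.fixture
def bulk_csv(tmp_path):
    """Factory writing a bulk CSV with the standard header from row tuples."""

    def _write(rows, header="sample_id,species,family,guild,season,tissue,d15N,d13C", name="bulk.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n" if rows else header + "\n")
        return path

    return _write
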