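import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def junction_tsv(tmp_path):
    """A small well-formed split-dialect junction table on disk."""
    p = tmp_path / "junctions.tsv"
    p.write_text(
        "sample_id\tevent_id\tincl_up\tincl_down\texcl\n"
        "s1\tE8\t15\t15\t15\n"
        "s1\tE10\t48\t48\t4\n"
        "s2\tE8\t0\t0\t10\n",
        encoding="utf-8",
    )
    return p


@pytest.fixture
def samples_tsv(tmp_path):
    p = tmp_path / "samples.tsv"
    p.write_text(
        "sample_id\ttissue\ttissue_group\tcondition\tstage\treplicate\n"
        "s1\tcortex\tneural\tWT\tadult\t1\n"
        "s2\tliver\tnon_neural\tWT\tadult\t1\n",
        encoding="utf-8",
    )
    return p
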