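import pytest

from repeatedit.repeat_quant import CAG_CBE, GAA_ABE


@pytest.fixture(params=["cag-cbe", "gaa-abe"])
def spec(request):
    return {"cag-cbe": CAG_CBE, "gaa-abe": GAA_ABE}[request.param]


@pytest.fixture
def write_fastq(tmp_path):
    """Write (id, bases, quals) records to a temporary FASTQ and return its path."""

    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, bases, quals in records:
                fh.write(f"@{rid}\n{bases}\n+\n{quals}\n")
        return path

    return _write
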