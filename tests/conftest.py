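from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def write_tsv(tmp_path):
    """Write tab-delimited lines to a temp file and return its path."""
    counter = {"n": 0}

    def _write(lines, name=None) -> Path:
        counter["n"] += 1
        path = tmp_path / (name or f"file{counter['n']}.tsv")
        path.write_text("\n".join("\t".join(line) for line in lines) + "\n")
        return path

    return _write


SKYLINE_HEADER = ["Peptide Sequence", "Precursor Charge", "Fragment Ion",
                  "Product Charge", "Replicate Name", "Area"]
METADATA_HEADER = ["Replicate Name", "Sample Type", "Day", "Replicate Index",
                   "Concentration Level", "Calibration Point"]
DILUTION_HEADER = ["Calibration Point", "Theoretical Concentration"]
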