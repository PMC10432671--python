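import pytest
from hypothesis import settings

from neovax import PipelineConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Candidate-funnel counts per (sample, allele): predicted, bound, immunogenic,
# displayed.  Used to build per-peptide flag tables for the summary stage.
FUNNEL_ROWS = [
    ("SW1360", "HLA-A*24:02", 4, 2, 0, 0),
    ("SW2163", "HLA-A*02:01", 10, 9, 4, 0),
    ("SW2163", "HLA-A*24:02", 9, 4, 0, 0),
    ("SW2183", "HLA-A*02:01", 14, 14, 10, 0),
    ("SW2183", "HLA-A*24:02", 20, 8, 0, 0),
    ("SW2388", "HLA-A*03:01", 9, 7, 0, 0),
    ("MDA-MB-231", "HLA-A*02:01", 27, 21, 16, 1),
]

PATIENT_SAMPLES = {"SW1360", "SW2163", "SW2183", "SW2388"}


def funnel_fixture(rows):
    """Expand per-group counts into per-peptide summarize_counts inputs."""
    predicted, binder_flags, responders, displayed = [], {}, [], set()
    for sample, allele, n_pred, n_bound, n_imm, n_disp in rows:
        for i in range(n_pred):
            pep = f"{sample}|{allele}|{i}"
            predicted.append((sample, allele, pep))
            binder_flags[pep] = i < n_bound
            if i < n_imm:
                responders.append(("donor1", pep, True))
            if i < n_disp:
                displayed.add(pep)
    return predicted, binder_flags, responders, displayed


@pytest.fixture
def cfg():
    return PipelineConfig()
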