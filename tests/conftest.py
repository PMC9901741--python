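import numpy as np
import pandas as pd
import pytest

from airatio.cohort_io import ExpressionMatrix, MarkerPanel


def make_panel(n_adaptive=2, n_innate=2, markers_per=2, n_excluded=0):
    """Small synthetic marker panel: ct_a*/ct_i*/ct_x* with g_* markers."""
    rows = []
    idx = 0
    for comp, prefix, count in (("adaptive", "ct_a", n_adaptive),
                                ("innate", "ct_i", n_innate),
                                ("excluded", "ct_x", n_excluded)):
        for i in range(count):
            for _ in range(markers_per):
                rows.append({"cell_type": f"{prefix}{i}", "gene": f"g{idx:03d}",
                             "compartment": comp})
                idx += 1
    return MarkerPanel(pd.DataFrame(rows))


@pytest.fixture
def small_panel():
    return make_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20230206)


def random_expression(panel, n_samples, rng, extra_genes=5, transform="log2p1"):
    """Random non-negative matrix covering the panel plus background genes."""
    genes = panel.genes + [f"bg{i}" for i in range(extra_genes)]
    vals = rng.uniform(0.0, 10.0, (len(genes), n_samples))
    samples = [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples),
                            transform)


@pytest.fixture
def clinical_frame():
    """Minimal valid clinical table covering the label vocabulary."""
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "gender": ["male", "female", "male", "female", "male", "female"],
        "cancer_type": ["AAA"] * 3 + ["BBB"] * 3,
        "age": [60, 55, 70, 48, 66, 59],
        "stage": ["I", "IIa", "IIIb", "IV", "II", "unknown"],
        "os_time": [100.0, 200.0, 300.0, 400.0, 500.0, 600.0],
        "os_event": [1, 0, 1, 1, 0, 1],
        "pfi_time": [80.0, 150.0, 250.0, 300.0, 450.0, 500.0],
        "pfi_event": [1, 1, 1, 0, 0, 1],
        "response": ["CR", "PR", "SD", "PD", "none", "PD"],
        "phenotype": ["inflamed", "desert", "none", "excluded", "none", "none"],
    })
    return df.set_index("sample_id", drop=False)
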