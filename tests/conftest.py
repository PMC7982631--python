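import pandas as pd
import pytest

from careindex.io import pivot_panel
from careindex.qci import fit_qci_from_panels
from careindex.synthetic import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def noiseless_run():
    """Small noiseless synthetic panel: (cells, pops, truth, panels)."""
    cfg = SyntheticConfig(n_locations=6, noise_sd=0.0, seed=11)
    cells, pops, truth = generate_panel(cfg)
    panels, exclusions = pivot_panel(cells)
    assert exclusions.empty
    return cells, pops, truth, panels


@pytest.fixture(scope="session")
def noisy_run():
    cfg = SyntheticConfig(n_locations=6, noise_sd=0.1, seed=11)
    cells, pops, truth = generate_panel(cfg)
    panels, _ = pivot_panel(cells)
    return cells, pops, truth, panels


@pytest.fixture(scope="session")
def fitted(noiseless_run):
    """(model, index vectors) fitted on the noiseless panel."""
    _, _, _, panels = noiseless_run
    return fit_qci_from_panels(panels)


def gbd_csv_text(rows):
    """Render cell tuples (measure, location, sex, age, year, metric, val,
    lower, upper) in the GBD results-tool export dialect."""
    header = "measure_name,location_name,sex_name,age_name,year,metric_name,val,upper,lower"
    lines = [header]
    for m, loc, sex, age, year, metric, val, lo, hi in rows:
        lines.append(f"{m},{loc},{sex},{age},{year},{metric},{val},{hi},{lo}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_gbd_csv(tmp_path):
    def _write(rows, name="burden.csv"):
        path = tmp_path / name
        path.write_text(gbd_csv_text(rows), encoding="utf-8")
        return path
    return _write
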