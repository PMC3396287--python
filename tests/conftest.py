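import numpy as np
import pandas as pd
import pytest

from minichip.normalize import RatioTrack
from minichip.peaks import Peak
from minichip.simulate import MarkSpec, SimulationConfig, build_promoter_model


def make_track(m, positions=None, chromosome="chr1", state="averaged",
               a=None, mark="H3K4me3", cell_type="stem", array_id="t",
               spacing=100):
    """Construct a RatioTrack from explicit M values for fixture tests."""
    m = np.asarray(m, dtype=float)
    if positions is None:
        positions = np.arange(len(m)) * spacing
    positions = np.asarray(positions)
    probes = pd.DataFrame({
        "probe_id": [f"{chromosome}P{p:09d}" for p in positions],
        "chromosome": chromosome,
        "position": positions,
        "m": m,
        "a": np.full(len(m), 10.0) if a is None else np.asarray(a, float),
    })
    return RatioTrack(array_id=array_id, mark=mark, cell_type=cell_type,
                      probes=probes, state=state)


def make_peak(start, end, tier="strict", score_log2=1.0, chrom="chr1",
              mark="H3K4me3", cell_type="stem", fdr=None, n_probes=4,
              score_pct=90.0):
    if fdr is None:
        fdr = {"strict": 0.01, "relaxed": 0.1, "discarded": 0.5}[tier]
    return Peak(chromosome=chrom, start=start, end=end, n_probes=n_probes,
                score_pct=score_pct, score_log2=score_log2,
                mean_m=score_log2, fdr=fdr, tier=tier, mark=mark,
                cell_type=cell_type)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=20, n_replicates=2,
        marks=[MarkSpec("H3K4me3", "activating", "tss_double_peak", 2.5, 0.5),
               MarkSpec("H3K27me3", "silencing", "broad_domain", 1.5, 0.3)],
        rng_seed=11)


@pytest.fixture(scope="session")
def small_model(small_config):
    return build_promoter_model(small_config)
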