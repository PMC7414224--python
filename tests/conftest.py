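import numpy as np
import pytest

from trcpipe.core import GenomeLayout
from trcpipe.replication import ConflictParams, compute_rfd, detect_initiation_zones
from trcpipe.simulate import SimConfig, simulate_genome, simulate_okseq, simulate_tracks
from trcpipe.tracks import SignalTrack


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1, dsb_fraction=0.25)


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """One default-scale simulation shared by all recovery tests."""
    layout, genes, truth = simulate_genome(default_config)
    counts = simulate_okseq(truth)
    params = ConflictParams()
    rfd = compute_rfd(counts, params)
    zones = detect_initiation_zones(rfd, params)
    tracks_control = simulate_tracks(truth, default_config.replace(condition="control"))
    tracks_shtop1 = simulate_tracks(truth, default_config.replace(condition="shTop1"))
    return {
        "config": default_config,
        "layout": layout,
        "genes": genes,
        "truth": truth,
        "counts": counts,
        "params": params,
        "rfd": rfd,
        "zones": zones,
        "control": tracks_control,
        "shTop1": tracks_shtop1,
    }


@pytest.fixture
def small_layout():
    return GenomeLayout.from_dict({"chr1": 100_000})


def make_track(layout, values_by_chrom, bin_size=1000, flavor="raw"):
    return SignalTrack(
        layout,
        bin_size,
        {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()},
        flavor,
    )


@pytest.fixture
def constant_track(small_layout):
    return make_track(small_layout, {"chr1": np.full(100, 3.0)})
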