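import numpy as np
import pytest

import rgelquant as rg


@pytest.fixture()
def render_cfg():
    return rg.GelRenderConfig(seed=1)


@pytest.fixture(scope="session")
def sim_gel():
    """One fully rendered synthetic gel (sample + ladder + empty) with truth.

    Uniform breakage at 8403 rNMPs on the 24 Mb genome — the magnitude of the
    RNase-H2-null, Rnr1-depleted strain — shared across tests that only read it.
    """
    gcfg = rg.GelRenderConfig(seed=1)
    bcfg = rg.GenomeBreakConfig(n_rnmp=8403, seed=11)
    rng = np.random.default_rng(11)
    fragments = rg.simulate_fragments(bcfg, rng)
    lane = rg.render_lane(fragments, gcfg, rng, lane_id="sample")
    ladder, truth = rg.render_ladder_lane(gcfg, rng)
    empty = rg.render_empty_lane(gcfg, rng)
    peaks = rg.detect_ladder_peaks(ladder, gcfg.ladder_sizes)
    cal = rg.fit_ladder(peaks)
    return {"break_cfg": bcfg, "render_cfg": gcfg, "fragments": fragments,
            "lane": lane, "ladder": ladder, "ladder_truth": truth,
            "empty": empty, "cal": cal}
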