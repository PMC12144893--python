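import numpy as np
import pytest

import pocketswitch as ps
from pocketswitch import metad as M
from pocketswitch import pipeline as P


@pytest.fixture(scope="session")
def dw_surface():
    return ps.make_double_well(5.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def exit_surface():
    return ps.make_exit_landscape()


@pytest.fixture(scope="session")
def dw_metad(dw_surface):
    """Converged well-tempered run on the double well at default parameters."""
    surf = dw_surface
    sim = ps.SimConfig(
        n_steps=2_000_000,
        time_step=0.002,
        save_stride=10,
        seed=11,
        initial_position=(surf.meta["minima"][0],),
    )
    mc = M.MetaDConfig(grid_min=surf.domain[0, 0], grid_max=surf.domain[0, 1])
    trajs, hills, bias = M.run_metad(surf, [], sim, mc)
    bias_avg = M.averaged_bias(hills, bias.grid, mc.bias_factor_gamma)
    return {
        "surface": surf,
        "sim": sim,
        "config": mc,
        "trajs": trajs,
        "hills": hills,
        "bias": bias,
        "bias_avg": bias_avg,
    }


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """Full default-configuration pipeline run (tethered-Z vs free-Z)."""
    outdir = tmp_path_factory.mktemp("pipeline_default")
    results = P.run_pipeline({"seed": 1}, outdir)
    return {"results": results, "outdir": outdir}


@pytest.fixture(scope="session")
def brute_force_free(exit_surface):
    """Direct Langevin first-passage pocket->outside on the free landscape."""
    return ps.brute_force_mfpt(
        exit_surface, [], "pocket", "outside",
        n_replicas=220, max_steps=60_000_000, seed=77,
    )


@pytest.fixture(scope="session")
def fixtures_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return ps.make_fixtures(seed=1, outdir=out)
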