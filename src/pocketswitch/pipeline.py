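"""End-to-end orchestration: landscapes → metadynamics → states → kinetics.

One ``RunConfig`` (YAML on disk, every default materialized) drives the full
analysis for each requested condition (tethered/free × E/Z isomer):

1. unbiased calibration run (jump-rate observable for the MaxCal matrix),
2. shared-bias multiple-walker well-tempered metadynamics,
3. free-energy reconstruction and final-bias reweighting,
4. fingerprint state decomposition pooled across conditions (so
   conditions are compared on matched state definitions),
5. MaxCal transition matrix + transition-path-theory kinetics with
   block-bootstrap uncertainties,
6. tethered-vs-free comparison and the in-pocket switching verdict.

Outputs are plain text: HILLS/COLVAR files, free-energy tables, a
deterministic ``results.json`` (byte-identical for identical config+seed)
and a timestamped run log.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import yaml

from . import maxcal, metad, plumed, states, toy_systems
from .dynamics import SimConfig, integrate
from .toy_systems import InvalidParameterError

logger = logging.getLogger("pocketswitch")

DEFAULT_CONFIG = {
    "landscape": {
        "bound_depth": 10.0,  # kT, orthosteric pocket depth (Z isomer)
        "bound_depth_E": 7.0,  # kT, pocket depth after switching to E
        "intermediate_depth": 4.0,
        "n_intermediates": 2,
        "lateral_stiffness": 20.0,
        "open_stiffness": 0.1,
    },
    "tether": {
        "spring_constant": 2.0,  # kT per length^2
        "flat_radius": 0.5,  # zero restraint below this extension
    },
    "sim": {
        "time_step": 0.004,
        "friction": 1.0,
        "kT": 1.0,
        "save_stride": 1,
        "calibration_steps": 200000,
        "metad_steps": 500000,  # per walker
    },
    "metad": {
        "hill_height_w0": 1.2,
        "hill_sigma": 0.15,
        "bias_factor_gamma": 8.0,
        "deposition_stride": 500,
        "n_walkers": 4,
        "n_grid": 512,
    },
    "states": {
        "contact_threshold": 2.0,
        # interpretive decomposition: coarse fingerprints, the cluster analogue
        "cluster_bin_width": 1.4,
        "cluster_floor": 1e-5,
        # kinetic discretization: bins fine against kT/|F'| so sqrt-flux
        # edges reproduce diffusive barrier crossing
        "kinetic_bin_width": 0.15,
        "kinetic_floor": 1e-6,
        "equilibration_fraction": 0.2,
    },
    "kinetics": {
        "lag_frames": 1,
        "n_resamples": 200,
        "block_frames": 10000,
        "switching_rate": 1.0,  # per reduced time; photoswitching is fast
    },
    "conditions": ["tethered-Z", "free-Z"],
    "seed": 1,
    "time_scale": 1.0,  # optional reduced-time -> physical-time factor
}


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs remain in the output directory."""


def resolve_config(config: dict | None) -> dict:
    """Fill every default so the persisted config is self-contained."""
    full = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(full.get(key), dict):
            unknown = set(val) - set(full[key])
            if unknown:
                raise InvalidParameterError(f"unknown config keys {sorted(unknown)} in {key!r}")
            full[key].update(val)
        elif key in full:
            full[key] = val
        else:
            raise InvalidParameterError(f"unknown config key {key!r}")
    for cond in full["conditions"]:
        tether, _, isomer = cond.partition("-")
        if tether not in ("tethered", "free") or isomer not in ("E", "Z"):
            raise InvalidParameterError(
                f"condition {cond!r} must be '(tethered|free)-(E|Z)'"
            )
    return full


def load_config(path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True, default_flow_style=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()[:16]


def build_surfaces(config: dict) -> dict:
    lc = config["landscape"]
    shared = {
        "intermediate_depth": lc["intermediate_depth"],
        "n_intermediates": lc["n_intermediates"],
        "lateral_stiffness": lc["lateral_stiffness"],
        "open_stiffness": lc["open_stiffness"],
    }
    surf_E, surf_Z = toy_systems.make_isomer_pair(
        shared, bound_depth_E=lc["bound_depth_E"], bound_depth_Z=lc["bound_depth"]
    )
    return {"E": surf_E, "Z": surf_Z}


def build_tether(config: dict, surface) -> toy_systems.RestraintTerm:
    tc = config["tether"]
    anchor = surface.meta.get("anchor", [surface.domain[0, 0], 0.0])
    return toy_systems.RestraintTerm(
        kind="tether",
        anchor=(float(anchor[0]), float(anchor[1])),
        spring_constant=tc["spring_constant"],
        flat_radius=tc["flat_radius"],
    )


def _round(x, nd=10):
    if isinstance(x, float):
        if math.isinf(x) or math.isnan(x):
            return repr(x)
        return round(x, nd)
    return x


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(float(v)) for v in obj.ravel()]
    if isinstance(obj, (np.floating, float)):
        return _round(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_condition(config: dict, condition: str, surfaces: dict, outdir: Path) -> dict:
    """Simulate, bias and reweight one condition; returns raw stage products."""
    sim = config["sim"]
    mc = config["metad"]
    tether_kind, _, isomer = condition.partition("-")
    surface = surfaces[isomer]
    restraints = [build_tether(config, surface)] if tether_kind == "tethered" else []
    start = tuple(surface.region_minimum("pocket"))
    seed = int(config["seed"])
    cond_seed = seed * 1000 + {"tethered-Z": 1, "free-Z": 2, "tethered-E": 3, "free-E": 4}[condition]

    logger.info("[%s] unbiased calibration run (%d steps)", condition, sim["calibration_steps"])
    calib = integrate(
        surface,
        restraints,
        None,
        SimConfig(
            n_steps=int(sim["calibration_steps"]),
            time_step=sim["time_step"],
            friction=sim["friction"],
            kT=sim["kT"],
            save_stride=int(sim["save_stride"]),
            seed=cond_seed,
            initial_position=start,
        ),
    )
    plumed.write_colvar(calib, outdir / f"COLVAR_calib.{condition}")

    logger.info(
        "[%s] metadynamics: %d walkers x %d steps", condition, mc["n_walkers"], sim["metad_steps"]
    )
    metad_cfg = metad.MetaDConfig(
        hill_height_w0=mc["hill_height_w0"],
        hill_sigma=mc["hill_sigma"],
        bias_factor_gamma=mc["bias_factor_gamma"],
        deposition_stride=int(mc["deposition_stride"]),
        n_walkers=int(mc["n_walkers"]),
        grid_min=float(surface.domain[0, 0]),
        grid_max=float(surface.domain[0, 1]),
        n_grid=int(mc["n_grid"]),
    )
    trajs, hills, bias = metad.run_metad(
        surface,
        restraints,
        SimConfig(
            n_steps=int(sim["metad_steps"]),
            time_step=sim["time_step"],
            friction=sim["friction"],
            kT=sim["kT"],
            save_stride=int(sim["save_stride"]),
            seed=cond_seed + 1,
            initial_position=start,
        ),
        metad_cfg,
    )
    plumed.write_hills(hills, outdir / f"HILLS.{condition}")
    for w, traj in enumerate(trajs):
        plumed.write_colvar(traj, outdir / f"COLVAR_walker{w}.{condition}")
    bias_avg = metad.averaged_bias(hills, bias.grid, metad_cfg.bias_factor_gamma)
    bias_avg.write(outdir / f"bias.{condition}.dat")
    fes = metad.free_energy_estimate(bias_avg)
    fes.write(outdir / f"fes.{condition}.dat")
    weights = metad.reweight(
        trajs, bias_avg, kT=sim["kT"],
        equilibration_fraction=config["states"]["equilibration_fraction"],
    )
    return {
        "surface": surface,
        "restraints": restraints,
        "calib": calib,
        "trajs": trajs,
        "bias": bias_avg,
        "fes": fes,
        "weights": weights,
        "seed": cond_seed,
    }


def run_pipeline(config: dict | None = None, outdir="pocketswitch_run") -> dict:
    """Execute the full analysis; returns the results dict written to disk."""
    config = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s [%(levelname)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        save_config(config, outdir / "config_resolved.yaml")
        logger.info("config hash %s, master seed %d", config_hash(config), config["seed"])
        surfaces = build_surfaces(config)
        for name, surf in surfaces.items():
            surf.save(outdir / f"surface_{name}.json")

        stage = "simulate/metad/reweight"
        products = {}
        for cond in config["conditions"]:
            products[cond] = run_condition(config, cond, surfaces, outdir)

        stage = "state decomposition"
        sc = config["states"]
        region_names = [r.name for r in surfaces["Z"].regions]

        def pooled_decomposition(bin_width, floor):
            # pooled clustering -> matched microstate definitions across conditions
            all_fp, all_w, by_cond = [], [], {}
            definition = None
            for cond, prod in products.items():
                fp, definition = states.featurize(
                    prod["weights"].cv,
                    prod["surface"],
                    contact_threshold=sc["contact_threshold"],
                    extension_bin_width=bin_width,
                )
                by_cond[cond] = fp
                all_fp.append(fp)
                all_w.append(prod["weights"].weights / len(products))
            dec = states.cluster_states(
                np.vstack(all_fp),
                np.concatenate(all_w),
                region_names=region_names,
                floor=floor,
                fingerprint_definition=definition,
            )
            return dec, by_cond

        cluster_dec, cluster_fp = pooled_decomposition(
            sc["cluster_bin_width"], sc["cluster_floor"]
        )
        kin_dec, kin_fp = pooled_decomposition(
            sc["kinetic_bin_width"], sc["kinetic_floor"]
        )
        logger.info(
            "decompositions: %d interpretive clusters, %d kinetic microstates, macrostates %s",
            cluster_dec.n_microstates,
            kin_dec.n_microstates,
            cluster_dec.macrostates,
        )

        stage = "kinetics"
        kc = config["kinetics"]
        frame_time = config["sim"]["time_step"] * config["sim"]["save_stride"]
        results = {
            "config_hash": config_hash(config),
            "seed": int(config["seed"]),
            "units": "reduced (kT=1, unit length, unit friction)",
            "time_scale": float(config["time_scale"]),
            "n_clusters": int(cluster_dec.n_microstates),
            "n_kinetic_microstates": int(kin_dec.n_microstates),
            "macrostates": cluster_dec.macrostates,
            "conditions": {},
        }
        kin_by_cond = {}
        # adjacency: union of observed connectivity over conditions (matched
        # topology), pruned to structurally adjacent states — over one lag
        # the ligand cannot cross an entire bin unseen
        adj = None
        for cond, prod in products.items():
            label_seqs = []
            for traj in prod["trajs"]:
                fp, _ = states.featurize(
                    traj.cv_values, prod["surface"],
                    contact_threshold=sc["contact_threshold"],
                    extension_bin_width=sc["kinetic_bin_width"],
                )
                label_seqs.append(kin_dec.assign(fp))
            prod["metad_labels"] = label_seqs
            a = states.connectivity(label_seqs, kin_dec, lag=int(kc["lag_frames"]))
            adj = a if adj is None else (adj | a)
        adj &= states.structural_adjacency(
            kin_dec,
            surfaces["Z"],
            contact_threshold=sc["contact_threshold"],
            extension_bin_width=sc["kinetic_bin_width"],
        )
        np.fill_diagonal(adj, True)

        for cond, prod in products.items():
            cond_cluster = states.StateDecomposition(
                microstate_label=cluster_dec.assign(cluster_fp[cond]),
                n_microstates=cluster_dec.n_microstates,
                fingerprints=cluster_dec.fingerprints,
                macrostate_of=cluster_dec.macrostate_of,
                fingerprint_definition=cluster_dec.fingerprint_definition,
            )
            pops = states.state_populations(
                cond_cluster,
                prod["weights"],
                kT=config["sim"]["kT"],
                n_boot=int(kc["n_resamples"]),
                block_frames=int(kc["block_frames"]),
                seed=prod["seed"] + 7,
            )
            cond_kin_dec = states.StateDecomposition(
                microstate_label=kin_dec.assign(kin_fp[cond]),
                n_microstates=kin_dec.n_microstates,
                fingerprints=kin_dec.fingerprints,
                macrostate_of=kin_dec.macrostate_of,
                fingerprint_definition=kin_dec.fingerprint_definition,
            )
            calib_fp, _ = states.featurize(
                prod["calib"].cv_values, prod["surface"],
                contact_threshold=sc["contact_threshold"],
                extension_bin_width=sc["kinetic_bin_width"],
            )
            calib_labels = [kin_dec.assign(calib_fp)]
            kin = maxcal.bootstrap_kinetics(
                cond_kin_dec,
                prod["weights"],
                calib_labels,
                frame_time,
                int(kc["lag_frames"]),
                adj,
                n_resamples=int(kc["n_resamples"]),
                block_frames=int(kc["block_frames"]),
                seed=prod["seed"] + 8,
                condition={"tethered": cond.startswith("tethered"), "isomer": cond[-1]},
            )
            kin_by_cond[cond] = kin
            results["conditions"][cond] = {
                "group_probability": _jsonable(pops.group_probability),
                "delta_F_groups_kT": {
                    f"{a}->{b}": [_jsonable(v), _jsonable(s)]
                    for (a, b), (v, s) in pops.delta_F_groups.items()
                },
                "mean_jump_rate": _jsonable(kin.mean_jump_rate),
                "lag_time": _jsonable(kin.lag_time),
                "mfpt": {
                    f"{a}->{b}": {"mean": _jsonable(v["mean"]), "sd": _jsonable(v["sd"])}
                    for (a, b), v in kin.mfpt.items()
                },
                "residence_time": {
                    m: {"mean": _jsonable(v["mean"]), "sd": _jsonable(v["sd"])}
                    for m, v in kin.residence_time.items()
                },
                "bootstrap_dropped": kin.n_resamples_dropped,
            }

        stage = "comparison"
        for isomer in ("Z", "E"):
            t_key, f_key = f"tethered-{isomer}", f"free-{isomer}"
            if t_key in kin_by_cond and f_key in kin_by_cond:
                report = maxcal.compare_conditions(
                    kin_by_cond[t_key], kin_by_cond[f_key], kc["switching_rate"]
                )
                results[f"comparison_{isomer}"] = _jsonable(report)

        payload = json.dumps(_jsonable(results), sort_keys=True, indent=1)
        (outdir / "results.json").write_text(payload + "\n")
        # in-memory products for downstream analysis; never serialized
        results["_objects"] = {
            "kinetics": kin_by_cond,
            "cluster_decomposition": cluster_dec,
            "kinetic_decomposition": kin_dec,
            "adjacency": adj,
            "products": products,
        }
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        return results
    except Exception as exc:  # annotate with the failing stage, keep partials
        logger.exception("stage %r failed", stage)
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_fixtures(seed: int, outdir) -> Path:
    """Small deterministic test artifacts: HILLS/COLVAR files, a 3-state
    MaxCal oracle case, and a birth–death MFPT case with its closed form."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), 31337])))

    hills = plumed.HillsLog(
        time=np.array([2.0, 4.0]),
        center=rng.uniform(0.5, 2.5, 2).round(6),
        sigma=np.array([0.15, 0.15]),
        height=np.array([1.2, 1.1]),
        biasf=np.array([8.0, 8.0]),
        walker_id=np.array([0, 1]),
    )
    plumed.write_hills(hills, outdir / "HILLS.fixture")
    times = np.arange(5) * 0.04
    cv = rng.uniform(0.5, 2.5, 5).round(6)
    from .dynamics import Trajectory

    traj = Trajectory(
        times=times, positions=cv[:, None], cv_values=cv,
        surface_label=[""] * 5, bias_at_frame=cv * 0.5,
    )
    plumed.write_colvar(traj, outdir / "COLVAR.fixture")

    pi = np.array([0.6, 0.3, 0.1])
    adjacency = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=bool)
    rate = 0.1
    p_star, cal = maxcal.exhaustive_maxcal(pi, adjacency, rate, resolution=1e-4)
    case = {
        "pi": pi.tolist(),
        "adjacency": adjacency.astype(int).tolist(),
        "mean_jump_rate": rate,
        "oracle_p": [[repr(float(v)) for v in row] for row in p_star],
        "oracle_caliber": repr(float(cal)),
    }
    (outdir / "maxcal_case.json").write_text(json.dumps(case, indent=1, sort_keys=True) + "\n")

    # 5-state birth-death chain with the nested-sum closed form
    up = np.array([0.3, 0.25, 0.2, 0.15])
    down = np.array([0.1, 0.12, 0.18, 0.2])
    h = np.empty(4)  # h[i] = mean steps from i to i+1
    h[0] = 1.0 / up[0]
    for i in range(1, 4):
        h[i] = 1.0 / up[i] + (down[i - 1] / up[i]) * h[i - 1]
    bd = {
        "p_up": up.tolist(),
        "p_down": down.tolist(),
        "mfpt_0_to_4_steps": repr(float(h.sum())),
    }
    (outdir / "birth_death_case.json").write_text(json.dumps(bd, indent=1, sort_keys=True) + "\n")
    return outdir
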