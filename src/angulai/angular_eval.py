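"""Per-angle method comparison: metrics, profiles, and the experiment driver.

Four LAI-estimation methods are compared at every view zenith angle on a
shared train/test partition: (1) published vegetation indices with a
linear LAI model, (2) the optimal two-band index (ND / SR / DVI forms)
found by exhaustive band search on the calibration set, (3) a
back-propagation neural network on the full 501-band spectrum, and
(4) NIPALS PLSR with cross-validated latent-variable selection.

Metrics are R2 = 1 - SSE/SST and RMSE = sqrt(mean squared error).
Validation-set R2 may be negative and is reported raw, never clamped.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .band_optimizer import r2_surface, select_optimum, export_surface, index_value
from .estimators import fit_linear, fit_plsr, select_components, train_bpnn
from .spectra_io import Dataset, Partition, band_at, make_partition, write_dataset
from .synthetic_canopy import CanopyConfig, default_config, generate_dataset
from .vi_catalog import catalog_names, compute_vi

__all__ = [
    "MethodResult",
    "AngularProfile",
    "r_squared",
    "rmse",
    "evaluate_across_vza",
    "decline_vs_nadir",
    "relative_improvement",
    "run_experiment",
    "derive_seeds",
]


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST.

    SSE = sum((O_i - P_i)^2), SST = sum((O_i - mean(O))^2).  May be
    negative for out-of-sample predictions; never clamped.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must share length >= 2")
    sst = ((o - o.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("observed values are constant; R2 undefined")
    return float(1.0 - ((o - p) ** 2).sum() / sst)


def rmse(observed, predicted) -> float:
    """Root mean square error sqrt(mean((P_i - O_i)^2)), in LAI units."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size == 0 or o.shape != p.shape:
        raise ValueError("observed and predicted must share nonzero length")
    return float(np.sqrt(((p - o) ** 2).mean()))


@dataclass
class MethodResult:
    method: str
    vza: float
    set: str  # "calibration" | "validation"
    r2: float
    rmse: float
    n: int
    metadata: dict = field(default_factory=dict)


@dataclass
class AngularProfile:
    method: str
    results: list[MethodResult]

    def r2_at(self, vza: float, set: str = "validation") -> float:
        for r in self.results:
            if r.vza == vza and r.set == set:
                return r.r2
        raise KeyError(f"no {set} result at vza={vza}")

    def vzas(self) -> list[float]:
        return sorted({r.vza for r in self.results})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": r.method,
                    "vza": r.vza,
                    "set": r.set,
                    "r2": r.r2,
                    "rmse": r.rmse,
                    "n": r.n,
                }
                for r in sorted(self.results, key=lambda r: (r.vza, r.set))
            ]
        )


def decline_vs_nadir(profile: AngularProfile, set: str = "validation") -> dict[float, float]:
    """Percent R2 decline relative to nadir: 100 * (r2(0) - r2(vza)) / r2(0).

    Undefined (NaN) everywhere if the nadir R2 is not positive.
    """
    r0 = profile.r2_at(0.0, set)
    out = {}
    for vza in profile.vzas():
        out[vza] = (
            float("nan") if r0 <= 0 else 100.0 * (r0 - profile.r2_at(vza, set)) / r0
        )
    return out


def relative_improvement(a, b) -> float:
    """Percent R2 improvement of method a over method b: 100 * (a - b) / b.

    Accepts MethodResult objects (which must share vza and set) or bare R2
    values.  Undefined (NaN) when the reference R2 is not positive.
    """
    if isinstance(a, MethodResult) and isinstance(b, MethodResult):
        if a.vza != b.vza or a.set != b.set:
            raise ValueError("results must share vza and evaluation set")
    ra = a.r2 if isinstance(a, MethodResult) else float(a)
    rb = b.r2 if isinstance(b, MethodResult) else float(b)
    if rb <= 0:
        return float("nan")
    return 100.0 * (ra - rb) / rb


# ------------------------------------------------------------ method runners

def _metrics(method, vza, y_cal, p_cal, y_val, p_val, meta) -> list[MethodResult]:
    return [
        MethodResult(method, vza, "calibration", r_squared(y_cal, p_cal),
                     rmse(y_cal, p_cal), len(y_cal), meta),
        MethodResult(method, vza, "validation", r_squared(y_val, p_val),
                     rmse(y_val, p_val), len(y_val), meta),
    ]


def _linear_predict(x_cal, y_cal, x_val):
    ok = np.isfinite(x_cal)
    model = fit_linear(x_cal[ok], y_cal[ok])
    p_cal = model.predict(np.where(np.isfinite(x_cal), x_cal, np.nanmean(x_cal)))
    p_val = model.predict(np.where(np.isfinite(x_val), x_val, np.nanmean(x_cal)))
    return model, p_cal, p_val, int((~ok).sum())


def _run_traditional_vi(cal: Dataset, val: Dataset, spec: dict, folds) -> list[MethodResult]:
    """Best published index at this angle, chosen by calibration R2."""
    names = spec.get("names") or catalog_names()
    best = None
    per_vi = []
    for name in names:
        x_cal = compute_vi(name, cal.spectra)
        x_val = compute_vi(name, val.spectra)
        if np.isfinite(x_cal).sum() < 3 or np.ptp(x_cal[np.isfinite(x_cal)]) == 0:
            continue
        model, p_cal, p_val, dropped = _linear_predict(x_cal, cal.lai, x_val)
        res = _metrics(
            f"vi:{name}", cal.spectra.vza, cal.lai, p_cal, val.lai, p_val,
            {"vi": name, "dropped": dropped, "slope": model.slope, "intercept": model.intercept},
        )
        per_vi.extend(res)
        if best is None or res[0].r2 > best[0].r2:
            best = res
    out = [
        dataclasses.replace(r, method="traditional_vi",
                            metadata={**r.metadata, "all_vi": per_vi})
        for r in best
    ]
    return out


def _run_optimal_index(cal: Dataset, val: Dataset, spec: dict, folds) -> list[MethodResult]:
    index_type = spec.get("index_type", "DVI")
    step = float(spec.get("step", 2.0))
    surface = r2_surface(cal, index_type, step=step)
    best = select_optimum(surface, cal)
    x_cal = index_value(index_type, band_at(cal.spectra, best.lambda1),
                        band_at(cal.spectra, best.lambda2))
    x_val = index_value(index_type, band_at(val.spectra, best.lambda1),
                        band_at(val.spectra, best.lambda2))
    model, p_cal, p_val, dropped = _linear_predict(x_cal, cal.lai, x_val)
    meta = {
        "index_type": index_type, "lambda1": best.lambda1, "lambda2": best.lambda2,
        "surface_r2": best.r2, "slope": model.slope, "intercept": model.intercept,
        "dropped": dropped, "surface": surface,
    }
    return _metrics(f"optimal_{index_type.lower()}", cal.spectra.vza,
                    cal.lai, p_cal, val.lai, p_val, meta)


def _run_plsr(cal: Dataset, val: Dataset, spec: dict, folds) -> list[MethodResult]:
    A_max = int(spec.get("A_max", 15))
    scale = bool(spec.get("scale", False))
    sel = select_components(cal.spectra.reflectance, cal.lai, A_max=A_max,
                            folds=folds, scale=scale)
    model = fit_plsr(cal.spectra.reflectance, cal.lai, sel.chosen, scale=scale)
    meta = {"n_components": sel.chosen, "cv_rmse": sel.cv_rmse, "model": model}
    return _metrics("plsr", cal.spectra.vza, cal.lai,
                    model.predict(cal.spectra.reflectance),
                    val.lai, model.predict(val.spectra.reflectance), meta)


def _run_bpnn(cal: Dataset, val: Dataset, spec: dict, folds) -> list[MethodResult]:
    model, report = train_bpnn(
        cal.spectra.reflectance, cal.lai,
        hidden_grid=tuple(spec.get("hidden_grid", (5, 10, 20, 50, 100, 200))),
        repeats=int(spec.get("repeats", 20)),
        epochs=int(spec.get("epochs", 500)),
        lr=float(spec.get("lr", 1e-2)),
        seed=int(spec.get("seed", 0)),
        folds=folds,
    )
    meta = {"hidden_size": model.hidden_size, "selection": report}
    return _metrics("bpnn", cal.spectra.vza, cal.lai,
                    model.predict(cal.spectra.reflectance),
                    val.lai, model.predict(val.spectra.reflectance), meta)


_RUNNERS = {
    "traditional_vi": _run_traditional_vi,
    "optimal_index": _run_optimal_index,
    "plsr": _run_plsr,
    "bpnn": _run_bpnn,
}


def evaluate_across_vza(
    datasets: dict[float, Dataset], method_spec: dict, partition: Partition
) -> AngularProfile:
    """Train/evaluate one method independently at every view zenith angle.

    ``method_spec`` carries a ``method`` key (traditional_vi, optimal_index,
    plsr, bpnn) plus method parameters.  All datasets must share sample ids
    with the partition; the calibration fold assignment is reused for every
    cross-validated selection so the whole profile is one-seed reproducible.
    """
    method = method_spec["method"]
    if method not in _RUNNERS:
        raise ValueError(f"unknown method {method!r}; known: {sorted(_RUNNERS)}")
    results: list[MethodResult] = []
    name = None
    for vza in sorted(datasets):
        ds = datasets[vza]
        if set(ds.sample_ids) != set(partition.train_ids) | set(partition.test_ids):
            raise ValueError(f"dataset at vza={vza} does not match the partition")
        cal = ds.subset(partition.train_ids)
        val = ds.subset(partition.test_ids)
        folds = np.array([partition.fold_assignment[s] for s in partition.train_ids])
        res = _RUNNERS[method](cal, val, method_spec, folds)
        name = res[0].method
        results.extend(res)
    return AngularProfile(method=name or method, results=results)


# ------------------------------------------------------------ experiment

def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Documented splitting scheme: child SeedSequences of the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


DEFAULT_EXPERIMENT = {
    "seed": 1,
    "simulate": {"vzas": list(range(-60, 61, 10))},
    "partition": {"n_train": 176, "k": 5, "shared": True},
    "optimize": {"step": 2.0, "types": ["ND", "SR", "DVI"]},
    "plsr": {"A_max": 15, "scale": False},
    "bpnn": {"hidden_grid": [10, 50], "repeats": 5, "epochs": 300, "lr": 0.01},
    "report": {"export_surfaces": True},
}


def run_experiment(config, out_dir) -> Path:
    """End-to-end driver: simulate -> indices -> band search -> PLSR/BPNN ->
    angular evaluation, writing a CSV report directory.

    ``config`` is a YAML path or a dict with sections seed / simulate /
    partition / optimize / plsr / bpnn / report.  All stage seeds derive
    from the one master seed, so a rerun is byte-identical.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_EXPERIMENT, **(config or {})}
    for k in ("simulate", "partition", "optimize", "plsr", "bpnn", "report"):
        cfg[k] = {**DEFAULT_EXPERIMENT.get(k, {}), **(cfg.get(k) or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[str] = [f"angulai {__version__}", f"master_seed {cfg['seed']}"]

    seeds = derive_seeds(int(cfg["seed"]), 3)
    sim_seed, part_seed, fit_seed = seeds
    log.append(f"derived seeds: simulate={sim_seed} partition={part_seed} fit={fit_seed}")

    # --- simulate or load
    sim = dict(cfg["simulate"])
    vzas = [float(v) for v in sim.pop("vzas")]
    if "spectra_paths" in sim:  # pre-measured input mode
        from .spectra_io import read_dataset

        datasets = {
            float(v): read_dataset(p, sim["lai_path"]) for v, p in sim["spectra_paths"].items()
        }
    else:
        base = CanopyConfig.from_yaml(sim["config"]) if sim.get("config") else default_config()
        overrides = {k: v for k, v in sim.items() if k != "config"}
        canopy = base.replace(seed=sim_seed, **overrides)
        datasets = generate_dataset(canopy, vzas)
        for vza, ds in datasets.items():
            tag = f"{int(vza):+d}" if vza < 0 or vza > 0 else "+0"
            write_dataset(ds, out / f"spectra_vza{tag}.csv", out / "lai.csv")
    log.append(f"{len(datasets)} VZA datasets, n={next(iter(datasets.values())).n_samples}")

    # --- shared partition
    any_ds = next(iter(datasets.values()))
    partition = make_partition(any_ds, n_train=int(cfg["partition"]["n_train"]),
                               k=int(cfg["partition"]["k"]), seed=part_seed)
    pd.DataFrame(
        {
            "sample_id": partition.train_ids + partition.test_ids,
            "set": ["calibration"] * len(partition.train_ids)
            + ["validation"] * len(partition.test_ids),
            "fold": [partition.fold_assignment[s] for s in partition.train_ids]
            + [0] * len(partition.test_ids),
        }
    ).to_csv(out / "partition.csv", index=False)

    # --- per-VI results at every angle
    vi_rows = []
    for vza in sorted(datasets):
        cal = datasets[vza].subset(partition.train_ids)
        val = datasets[vza].subset(partition.test_ids)
        for name in catalog_names():
            x_cal, x_val = compute_vi(name, cal.spectra), compute_vi(name, val.spectra)
            ok = np.isfinite(x_cal)
            if ok.sum() < 3 or np.ptp(x_cal[ok]) == 0:
                continue
            _, p_cal, p_val, dropped = _linear_predict(x_cal, cal.lai, x_val)
            vi_rows.append({
                "vza": vza, "index": name,
                "r2_cal": r_squared(cal.lai, p_cal), "rmse_cal": rmse(cal.lai, p_cal),
                "r2_val": r_squared(val.lai, p_val), "rmse_val": rmse(val.lai, p_val),
                "n_dropped": dropped,
            })
    pd.DataFrame(vi_rows).to_csv(out / "vi_results.csv", index=False, float_format="%.12g")

    # --- profiles for the four methods
    method_specs = {
        "traditional_vi": {"method": "traditional_vi"},
        "optimal_dvi": {"method": "optimal_index", "index_type": "DVI",
                        "step": cfg["optimize"]["step"]},
        "plsr": {"method": "plsr", **cfg["plsr"]},
        "bpnn": {"method": "bpnn", **cfg["bpnn"], "seed": fit_seed},
    }
    profiles: dict[str, AngularProfile] = {}
    for label, spec in method_specs.items():
        profiles[label] = evaluate_across_vza(datasets, spec, partition)
        profiles[label].to_frame().to_csv(
            out / f"profile_{label}.csv", index=False, float_format="%.12g"
        )
        log.append(f"profile {label} done at {time.time() - t0:.1f}s")

    # --- optimal band pairs for all three index forms (calibration search)
    pair_rows = []
    for index_type in cfg["optimize"]["types"]:
        for vza in sorted(datasets):
            cal = datasets[vza].subset(partition.train_ids)
            val = datasets[vza].subset(partition.test_ids)
            surface = r2_surface(cal, index_type, step=float(cfg["optimize"]["step"]))
            best = select_optimum(surface, cal)
            x_val = index_value(index_type, band_at(val.spectra, best.lambda1),
                                band_at(val.spectra, best.lambda2))
            p_val = best.slope * np.where(np.isfinite(x_val), x_val, 0) + best.intercept
            pair_rows.append({
                "index_type": index_type, "vza": vza,
                "lambda1": best.lambda1, "lambda2": best.lambda2,
                "r2_cal": best.r2,
                "r2_val": r_squared(val.lai, p_val), "rmse_val": rmse(val.lai, p_val),
            })
            if cfg["report"].get("export_surfaces", True):
                tag = f"{int(vza):+d}"
                export_surface(surface, out / f"surface_{index_type}_vza{tag}.csv")
    pd.DataFrame(pair_rows).to_csv(
        out / "optimal_pairs.csv", index=False, float_format="%.12g"
    )  # calibration-set R2, validation metrics alongside

    # --- PLSR diagnostics at nadir (if present)
    if 0.0 in datasets:
        cal0 = datasets[0.0].subset(partition.train_ids)
        folds = np.array([partition.fold_assignment[s] for s in partition.train_ids])
        sel = select_components(cal0.spectra.reflectance, cal0.lai,
                                A_max=int(cfg["plsr"]["A_max"]), folds=folds,
                                scale=bool(cfg["plsr"]["scale"]))
        pd.DataFrame({"A": sel.candidates, "cv_rmse": sel.cv_rmse}).to_csv(
            out / "plsr_rmse_curve.csv", index=False, float_format="%.12g"
        )
        model = fit_plsr(cal0.spectra.reflectance, cal0.lai, sel.chosen,
                         scale=bool(cfg["plsr"]["scale"]))
        wl = cal0.spectra.grid.wavelengths
        pd.DataFrame(
            {"wavelength": wl}
            | {f"loading_{a}": model.x_loadings[:, a - 1]
               for a in range(1, min(3, model.n_components) + 1)}
        ).to_csv(out / "plsr_loadings.csv", index=False, float_format="%.12g")

    # --- decline table (needs a nadir result and >1 angle)
    if 0.0 in datasets and len(datasets) > 1:
        rows = []
        for label, prof in profiles.items():
            for set_name in ("calibration", "validation"):
                for vza, pct in decline_vs_nadir(prof, set_name).items():
                    rows.append({"method": label, "set": set_name, "vza": vza,
                                 "decline_pct": pct})
        pd.DataFrame(rows).to_csv(out / "decline_vs_nadir.csv", index=False,
                                  float_format="%.12g")

    log.append(f"total {time.time() - t0:.1f}s")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    cfg_out = {k: v for k, v in cfg.items()}
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg_out, fh, sort_keys=False)
    return out
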