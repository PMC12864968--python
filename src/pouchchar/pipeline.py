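"""End-to-end study pipeline: CSV inputs in, report tables out.

`run_pipeline` chains the stages in study order — dissolution fits, the
equivalence matrix against a named reference product, particle-size
statistics, density-derived flowability/porosity, and the physicochemical
panel — writing one CSV per report table plus a JSON manifest (package and
library versions, seed, option echo, input checksums, and the operation that
produced each column). Output is deterministic for fixed inputs; a stage
failure aborts with a stage-tagged error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dissolution import average_profile, fit_first_order, predict_percent_released
from .equivalence import compare_profiles
from .errors import StageError, ValidationError
from .particles import ParticleSample, sample_stats
from .physchem import FlowCurve, SolubilityMeasurement, flow_curve_summary, oven_volatiles_pct, percent_soluble
from .powder import TappedSeries, select_pycnometer_runs, summarize_density, tapped_density_converge, untapped_bulk_density
from .synthetic import read_dissolution_csv

__all__ = [
    "StudyConfig",
    "run_pipeline",
    "equivalence_matrix",
    "round_half_up",
    "simulate_study_inputs",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero to `ndigits` decimals (report convention)."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StudyConfig:
    """Paths and options driving one pipeline run."""

    products: tuple
    reference: str
    dissolution_csv: str
    particles_csv: dict      # product -> path
    density_csv: str
    physchem_csv: str
    flow_curve_csv: dict = field(default_factory=dict)  # product -> path
    cap_85: bool = False
    prediction_time_min: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.reference not in self.products:
            raise ValidationError(f"reference {self.reference!r} not among products")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["products"] = tuple(raw["products"])
        return cls(**raw)

    def required_files(self):
        yield self.dissolution_csv
        yield self.density_csv
        yield self.physchem_csv
        yield from self.particles_csv.values()
        yield from self.flow_curve_csv.values()


def equivalence_matrix(profiles_by_product: dict, reference: str, cap_85: bool = False) -> pd.DataFrame:
    """f1/f2/decision of every non-reference product against the reference.

    Profiles compared are the mean percent-of-total-release curves across
    replicates, mirroring product-level profile comparison.
    """
    if reference not in profiles_by_product:
        raise ValidationError(f"unknown reference product {reference!r}")

    def mean_percent_curve(profiles):
        m = average_profile(profiles)
        return 100.0 * m.mean_mg / m.mean_mg[-1]

    ref_curve = mean_percent_curve(profiles_by_product[reference])
    rows = []
    for product in profiles_by_product:
        if product == reference:
            continue
        res = compare_profiles(
            ref_curve, mean_percent_curve(profiles_by_product[product]),
            reference_name=reference, test_name=product, cap_85=cap_85,
        )
        rows.append({
            "reference": reference,
            "test": product,
            "f1": round_half_up(res.f1, 1),
            "f2": round_half_up(res.f2, 1),
            "equivalent": "Yes" if res.equivalent else "No",
            "n_timepoints": res.n_timepoints_used,
        })
    return pd.DataFrame(rows)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _split_list(cell) -> list[float]:
    return [float(x) for x in str(cell).split(";") if str(x).strip()]


def _stage_dissolution(config) -> tuple[pd.DataFrame, dict]:
    profiles = read_dissolution_csv(config.dissolution_csv)
    rows = []
    for product in config.products:
        if product not in profiles:
            raise ValidationError(f"no dissolution profiles for {product!r}")
        reps = profiles[product]
        mean = average_profile(reps)
        fit = fit_first_order(mean.times, mean.mean_mg)
        per_rep = [fit_first_order(r) for r in reps]
        rows.append({
            "product": product,
            "M0_mg": round_half_up(fit.M0, 3),
            "k_per_min": round_half_up(fit.k, 3),
            "k_replicate_sd": round_half_up(
                float(np.std([f.k for f in per_rep], ddof=1)) if len(per_rep) > 1 else 0.0, 4),
            "pct_released_60min": round_half_up(
                predict_percent_released(fit, config.prediction_time_min), 0),
            "converged": fit.converged,
        })
    return pd.DataFrame(rows), profiles


def _stage_psd(config) -> pd.DataFrame:
    rows = []
    for product in config.products:
        path = config.particles_csv.get(product)
        if path is None or not Path(path).exists():
            raise ValidationError(f"missing particle file for {product!r}: {path}")
        sample = ParticleSample(pd.read_csv(path)["diameter_um"].to_numpy())
        for weighting in ("q3", "q0"):
            s = sample_stats(sample, weighting)
            rows.append({
                "product": product, "weighting": weighting,
                "mean_um": round_half_up(s.mean, 2),
                "d10_um": round_half_up(s.d10, 2),
                "d50_um": round_half_up(s.d50, 2),
                "d90_um": round_half_up(s.d90, 2),
                "span": round_half_up(s.span, 2),
            })
    return pd.DataFrame(rows)


def _stage_density(config) -> pd.DataFrame:
    df = pd.read_csv(config.density_csv).set_index("product")
    rows = []
    for product in config.products:
        if product not in df.index:
            raise ValidationError(f"no density record for {product!r}")
        rec = df.loc[product]
        rho_ub = untapped_bulk_density(float(rec["untapped_mass_g"]),
                                       float(rec.get("cup_volume_mL", 25.0)))
        series = TappedSeries(filler_mass=float(rec["tap_mass_g"]),
                              volumes=tuple(_split_list(rec["tap_volumes_mL"])))
        _, rho_tb = tapped_density_converge(series)
        _, rho_t, _ = select_pycnometer_runs(_split_list(rec["pyc_densities"]))
        summary = summarize_density(product, rho_ub, rho_tb, rho_t)
        rows.append({
            "product": product,
            "rho_UB": round_half_up(summary.rho_UB, 4),
            "rho_TB": round_half_up(summary.rho_TB, 3),
            "rho_T": round_half_up(summary.rho_T, 3),
            "carr_index": round_half_up(summary.carr_index, 2),
            "hausner_ratio": round_half_up(summary.hausner_ratio, 3),
            "porosity_pct": round_half_up(summary.porosity, 3),
            "flow_class": summary.flow_class.label,
            "flow_concordant": summary.flow_class.concordant,
        })
    return pd.DataFrame(rows)


def _stage_physchem(config) -> pd.DataFrame:
    df = pd.read_csv(config.physchem_csv).set_index("product")
    rows = []
    for product in config.products:
        if product not in df.index:
            raise ValidationError(f"no physchem record for {product!r}")
        rec = df.loc[product]
        if pd.isna(rec["m_final_g"]):
            soluble = np.nan  # unfiltrable sample: missing, never 0
        else:
            soluble = percent_soluble(SolubilityMeasurement(
                m_filler=float(rec["m_filler_g"]),
                m_paper=float(rec["m_paper_g"]),
                m_final=float(rec["m_final_g"]),
            ))
        row = {
            "product": product,
            "percent_soluble": round_half_up(soluble, 2) if np.isfinite(soluble) else "N/A",
            "ov_pct_mc": round_half_up(
                oven_volatiles_pct(float(rec["ov_mass_before_g"]),
                                   float(rec["ov_mass_after_g"])), 2),
            "pH": round_half_up(float(rec["pH"]), 2),
            "water_activity": round_half_up(float(rec["water_activity"]), 2),
        }
        fc_path = config.flow_curve_csv.get(product)
        if fc_path:
            fc = pd.read_csv(fc_path)
            mean_visc, flow_idx = flow_curve_summary(FlowCurve(
                fc["shear_rate_per_s"].to_numpy(), fc["viscosity_cP"].to_numpy()))
            row["mean_viscosity_cP"] = round_half_up(mean_visc, 2)
            row["flow_index"] = round_half_up(flow_idx, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig, out_dir) -> dict:
    """Execute all stages and write report CSVs plus a manifest under out_dir.

    Returns {table name: written path}. Any stage failure raises StageError
    after removing files written so far.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in config.required_files():
        if not Path(path).exists():
            raise StageError("inputs", f"missing input file: {path}")

    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    stages = {}
    try:
        table, profiles = _run(_stage_dissolution, "dissolution", config)
        emit("table_dissolution", table)
        stages["table_dissolution"] = "fit_first_order/predict_percent_released"

        emit("table_equivalence",
             _run(lambda c: equivalence_matrix(profiles, c.reference, c.cap_85),
                  "equivalence", config))
        stages["table_equivalence"] = "difference_factor_f1/similarity_factor_f2/assess_equivalence"

        emit("table_psd", _run(_stage_psd, "psd", config))
        stages["table_psd"] = "sample_stats/span"

        emit("table_density", _run(_stage_density, "density", config))
        stages["table_density"] = ("untapped_bulk_density/tapped_density_converge/"
                                   "select_pycnometer_runs/carr_index/hausner_ratio/"
                                   "porosity_percent/classify_flow")

        emit("table_physchem", _run(_stage_physchem, "physchem", config))
        stages["table_physchem"] = "percent_soluble/oven_volatiles_pct/flow_curve_summary"
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise

    manifest = {
        "pouchchar_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "options": {"cap_85": config.cap_85,
                    "prediction_time_min": config.prediction_time_min,
                    "reference": config.reference},
        "inputs_sha256": {str(p): _sha256(p) for p in sorted(set(config.required_files()))},
        "producing_operations": stages,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path
    return {k: str(v) for k, v in written.items()}


def simulate_study_inputs(out_dir, seed: int = 0, n_replicates: int = 12,
                          n_particles: int = 20_000) -> StudyConfig:
    """Write a complete synthetic input set emulating the seven-product study.

    Dissolution replicates are drawn at each product's reference (M0, k) with
    5% replicate CV and 2% of M0 additive noise; particle populations are
    unimodal lognormals for the Gaussian-like products (on!, Zyn, Rogue) and
    bimodal (fines + granule mode) for the rest; tap series, pycnometer runs,
    solubility/OV/pH/water-activity records, and flow curves are generated to
    land near the products' reference values. Returns a StudyConfig wired to
    the written files. Fully deterministic under `seed`.
    """
    from .study import DENSITIES, KINETICS, PHYSCHEM_PANEL, PRODUCTS, PSD_INTERCEPTS
    from .synthetic import (
        DissolutionScenario, FlowCurveScenario, ParticleScenario,
        PycnometerScenario, TapScenario, gen_dissolution, gen_flow_curve,
        gen_particles, gen_pycnometer_runs, gen_tap_series,
        write_dissolution_csv, write_flow_curve_csv, write_particles_csv,
    )
    from .powder import run_density

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = iter(rng.integers(0, 2**31 - 1, size=8 * len(PRODUCTS)))

    unimodal = {"on!", "Zyn", "Rogue"}
    profiles = []
    particles_csv = {}
    flow_csv = {}
    density_rows = []
    phys_rows = []
    visc_K = {"on!": 1.3, "Zyn": 1.6, "Velo": 1.25, "Dryft": 1.3,
              "Rogue": 1.1, "Volt": 1.1, "Loop": 2.25}
    for product in PRODUCTS:
        m0, k = KINETICS[product]
        profiles.extend(gen_dissolution(DissolutionScenario(
            product, m0, k, M0_cv=0.05, k_cv=0.05, noise_sd=0.02 * m0,
            n_replicates=n_replicates, seed=int(next(sub)))))

        d50_q3 = PSD_INTERCEPTS["q3"][product]["d50"]
        if product in unimodal:
            modes = ((d50_q3, 1.45, 1.0),)
        else:
            fines = PSD_INTERCEPTS["q0"][product]["d50"]
            modes = ((fines, 1.35, 0.6), (d50_q3, 1.3, 0.4))
        diam = gen_particles(ParticleScenario(modes=modes, n_particles=n_particles,
                                              seed=int(next(sub))))
        ppath = out / f"particles_{product.strip('!').lower()}.csv"
        write_particles_csv(diam, ppath)
        particles_csv[product] = str(ppath)

        dens = DENSITIES[product]
        tap = gen_tap_series(TapScenario(
            filler_mass=100.0, V0=100.0 / dens["rho_UB"],
            V_inf=100.0 / dens["rho_TB"], tau_taps=400.0,
            read_resolution=0.1, seed=int(next(sub))))
        pyc = gen_pycnometer_runs(PycnometerScenario(
            true_density=dens["rho_T"], seed=int(next(sub))))
        density_rows.append({
            "product": product,
            "untapped_mass_g": dens["rho_UB"] * 25.0,
            "cup_volume_mL": 25.0,
            "tap_mass_g": tap.filler_mass,
            "tap_volumes_mL": ";".join(f"{v:.9g}" for v in tap.volumes),
            "pyc_densities": ";".join(f"{run_density(r):.9g}" for r in pyc),
        })

        panel = PHYSCHEM_PANEL[product]
        soluble = panel["percent_soluble"]
        phys_rows.append({
            "product": product,
            "m_filler_g": 1.0,
            "m_paper_g": 1.0,
            "m_final_g": np.nan if soluble is None else 1.0 + (100.0 - soluble) / 100.0,
            "ov_mass_before_g": 2.0,
            "ov_mass_after_g": 2.0 * (1.0 - panel["ov_pct_mc"] / 100.0),
            "pH": panel["pH"],
            "water_activity": panel["aw"],
        })

        fc = gen_flow_curve(FlowCurveScenario(
            K=visc_K[product], n_exponent=-0.02 if product == "Loop" else 0.0,
            noise_cv=0.005, seed=int(next(sub))))
        fpath = out / f"flow_{product.strip('!').lower()}.csv"
        write_flow_curve_csv(fc, fpath)
        flow_csv[product] = str(fpath)

    diss_path = out / "dissolution.csv"
    write_dissolution_csv(profiles, diss_path)
    dens_path = out / "density.csv"
    pd.DataFrame(density_rows).to_csv(dens_path, index=False, float_format="%.9g")
    phys_path = out / "physchem.csv"
    pd.DataFrame(phys_rows).to_csv(phys_path, index=False, float_format="%.9g")

    return StudyConfig(
        products=tuple(PRODUCTS),
        reference="on!",
        dissolution_csv=str(diss_path),
        particles_csv=particles_csv,
        density_csv=str(dens_path),
        physchem_csv=str(phys_path),
        flow_curve_csv=flow_csv,
        seed=seed,
    )


def _run(fn, stage: str, config):
    try:
        return fn(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
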