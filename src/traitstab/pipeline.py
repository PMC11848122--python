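"""End-to-end orchestration: impute -> matrices -> distances -> stability ->
inference -> mock simulation, with a manifest recording every flag and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .constants import TRAIT_GROUPS, ConfigurationError, TraitstabError
from .imputation import (
    fit_all_trait_models,
    impute_survey_traits,
    model_summary,
    species_to_family_map,
)
from .inference import envfit, permanova, simper_year_to_centroid, simper_year_to_year
from .io import (
    ensure_exists,
    read_feeding_mode_csv,
    read_survey_csv,
    read_trait_measurements_csv,
    write_distance_csv,
    write_matrix_csv,
)
from .matrices import aggregate_by_feeding_mode, build_abundance_matrix, build_trait_matrix
from .mocksim import MockConfig, run_mock_experiment
from .multivariate import bray_curtis, nmds
from .stability import (
    stability_anova,
    stability_report,
    stability_table,
    year_to_centroid,
    year_to_year,
)
from .synth import (
    SynthConfig,
    feeding_mode_lookup,
    generate_species_pool,
    simulate_survey,
    simulate_trait_measurements,
    write_feeding_mode_csv,
    write_survey_csv,
    write_trait_measurements_csv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, mode flags and the run seed for the full analysis."""

    survey_csv: str
    traits_csv: str
    lookup_csv: str
    out_dir: str = "traitstab_out"
    seed: int = 0
    # stage flags (all design decisions are explicit and recorded in the manifest)
    averaging: str = "two_stage"           # abundance averaging scheme
    centroid: str = "mean"                 # betadisper centre: mean | median
    y2c_mode: str = "pcoa_centroid"        # year-to-centroid: pcoa_centroid | raw_to_mean
    clamp_negative: bool = True            # clamp negative CWM cells at 0
    trait_rescale: bool = False            # min-max rescale trait columns
    basis_dim: int = 10
    per_taxon_smooth: bool = False
    nmds_k: int = 2
    nmds_starts: int = 20
    n_perm: int = 999
    mock_dims: tuple[int, ...] = (13, 8)
    mock_reps: int = 100

    def validate(self) -> None:
        for p, kind in [
            (self.survey_csv, "survey"),
            (self.traits_csv, "trait measurement"),
            (self.lookup_csv, "feeding-mode lookup"),
        ]:
            ensure_exists(p, kind)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mock_dims"] = list(self.mock_dims)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except TraitstabError as exc:
                raise TraitstabError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_full_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every analysis stage and write the result bundle to ``out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict = {}
    counts: dict = {}

    survey = _stage("read_survey")(read_survey_csv)(cfg.survey_csv)
    measurements = _stage("read_traits")(read_trait_measurements_csv)(cfg.traits_csv)
    lookup = _stage("read_lookup")(read_feeding_mode_csv)(cfg.lookup_csv)
    counts["survey_rows"] = len(survey)
    counts["measurement_rows"] = len(measurements)

    # --- trait imputation ---------------------------------------------------
    models = _stage("fit_models")(fit_all_trait_models)(
        measurements, basis_dim=cfg.basis_dim, per_taxon_smooth=cfg.per_taxon_smooth
    )
    summary = model_summary(models)
    summary.to_csv(out / "model_summary.csv", index=False)
    tables["model_summary"] = summary

    sp2fam = species_to_family_map(measurements)
    if "family" in lookup.columns:
        sp2fam = {**sp2fam, **dict(zip(lookup["species"], lookup["family"]))}
    predictions = _stage("impute")(impute_survey_traits)(models, survey, sp2fam)
    counts["prediction_rows"] = len(predictions)

    # --- community matrices -------------------------------------------------
    A = _stage("abundance_matrix")(build_abundance_matrix)(survey, cfg.averaging)
    T = _stage("trait_matrix")(build_trait_matrix)(
        predictions, clamp_negative=cfg.clamp_negative, rescale=cfg.trait_rescale
    )
    modes = _stage("mode_matrix")(aggregate_by_feeding_mode)(A, lookup)
    write_matrix_csv(A, out / "abundance_matrix.csv")
    write_matrix_csv(T, out / "trait_matrix.csv")
    write_matrix_csv(modes, out / "feeding_mode_matrix.csv")
    tables.update(abundance=A, traits=T, feeding_modes=modes)

    # --- distances and ordinations ------------------------------------------
    D_sp = bray_curtis(A)
    D_tr = bray_curtis(T)
    write_distance_csv(D_sp, out / "distance_species.csv")
    write_distance_csv(D_tr, out / "distance_traits.csv")
    ords = {}
    for name, D in [("species", D_sp), ("traits", D_tr)]:
        o = nmds(D, k=cfg.nmds_k, n_starts=cfg.nmds_starts, seed=cfg.seed)
        o.to_dataframe().to_csv(out / f"nmds_{name}.csv")
        (out / f"nmds_{name}_stress.txt").write_text(
            f"stress={o.stress:.6f} converged={o.converged} n_starts={o.n_starts}\n"
        )
        ords[name] = o
    tables["ordinations"] = ords

    # --- stability ----------------------------------------------------------
    matrices = {"species": A, "trait": T}
    distances = {"species": D_sp, "trait": D_tr}
    stab_tables = {}
    for metric in ("year_to_centroid", "year_to_year"):
        by_type = {}
        for ct in ("species", "trait"):
            if metric == "year_to_centroid":
                d = year_to_centroid(
                    distances[ct], mode=cfg.y2c_mode, M=matrices[ct],
                    centroid=cfg.centroid,
                )
            else:
                d = year_to_year(distances[ct])
            by_type[ct] = d
        table = stability_table(by_type)
        table.to_csv(out / f"stability_{metric}.csv", index=False)
        aov = stability_anova(table)
        aov.to_csv(out / f"anova_{metric}.csv", index=False)
        (out / f"stability_{metric}_report.txt").write_text(stability_report(table))
        stab_tables[metric] = {"table": table, "anova": aov}
    tables["stability"] = stab_tables

    # --- PERMANOVA ----------------------------------------------------------
    perm_tables = {}
    for ct, D in distances.items():
        ponds = [l[0] for l in D.labels]
        years = [l[1] for l in D.labels]
        pt = permanova(D, ponds, years, n_perm=cfg.n_perm, seed=cfg.seed)
        pt.to_csv(out / f"permanova_{ct}.csv", index=False)
        perm_tables[ct] = pt
    tables["permanova"] = perm_tables

    # --- SIMPER -------------------------------------------------------------
    mode_map = dict(zip(lookup["species"], lookup["feeding_mode"]))
    simper_tables = {}
    for ct, M in matrices.items():
        gm = TRAIT_GROUPS if ct == "trait" else mode_map
        y2c = simper_year_to_centroid(M)
        y2y = simper_year_to_year(M, group_map=gm)
        y2c.comparisons.to_csv(out / f"simper_y2c_{ct}.csv", index=False)
        y2y.comparisons.to_csv(out / f"simper_y2y_{ct}.csv", index=False)
        y2y.summary.to_csv(out / f"simper_y2y_{ct}_summary.csv", index=False)
        simper_tables[ct] = {"year_to_centroid": y2c, "year_to_year": y2y}
    tables["simper"] = simper_tables

    # --- envfit on the trait ordination -------------------------------------
    env_tables = {}
    for name, V in [("species", A), ("feeding_mode", modes)]:
        et = envfit(ords["traits"], V, n_perm=cfg.n_perm, seed=cfg.seed)
        et.to_csv(out / f"envfit_{name}.csv", index=False)
        env_tables[name] = et
    tables["envfit"] = env_tables

    # --- mock-community control ---------------------------------------------
    mock_results = {}
    for nd in cfg.mock_dims:
        nd_eff = min(nd, A.shape[1], T.shape[1])
        mc = MockConfig(n_dims=nd_eff, n_reps=cfg.mock_reps, seed=cfg.seed)
        res = run_mock_experiment(A, T, mc)
        res.per_rep.to_csv(out / f"mocksim_dims{nd_eff}.csv", index=False)
        (out / f"mocksim_dims{nd_eff}_summary.txt").write_text(res.report())
        mock_results[nd_eff] = res
    tables["mocksim"] = mock_results

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "counts": counts,
        "nmds_stress": {k: o.stress for k, o in ords.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return PipelineResult(config=cfg, tables=tables, manifest=manifest)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------
_PRESETS = {
    # tiny keeps the fixed 13-trait vocabulary; dims are survey dims only
    "tiny": dict(n_ponds=3, n_years=4, n_months=3, n_stations=2, n_species=6,
                 mode_split=None),
    "paper_shape": dict(n_ponds=6, n_years=6, n_months=6, n_stations=2,
                        n_species=27, mode_split=(3, 6, 9, 9)),
}


def make_fixture(
    preset: str,
    seed: int,
    out_dir: str,
    redundancy: float = 0.5,
    compensation: float = 0.0,
    temporal_cv: float = 0.5,
    spatial_filter_strength: float = 0.5,
    n_per_species: int = 20,
    noise_sd: float = 0.05,
) -> dict[str, Path]:
    """Write a synthetic survey/trait/lookup fixture directory."""
    if preset not in _PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; use {sorted(_PRESETS)}")
    p = _PRESETS[preset]
    pool = generate_species_pool(
        p["n_species"], redundancy, seed, mode_split=p["mode_split"]
    )
    cfg = SynthConfig(
        n_ponds=p["n_ponds"], n_years=p["n_years"], n_months=p["n_months"],
        n_stations=p["n_stations"], species_pool=tuple(pool),
        redundancy=redundancy, compensation=compensation,
        temporal_cv=temporal_cv, spatial_filter_strength=spatial_filter_strength,
        seed=seed,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey = simulate_survey(cfg)
    measurements = simulate_trait_measurements(cfg, n_per_species, noise_sd)
    lookup = feeding_mode_lookup(pool)
    paths = {
        "survey": out / "survey.csv",
        "traits": out / "trait_measurements.csv",
        "lookup": out / "feeding_modes.csv",
    }
    write_survey_csv(survey, paths["survey"])
    write_trait_measurements_csv(measurements, paths["traits"])
    write_feeding_mode_csv(lookup, paths["lookup"])
    (out / "fixture.json").write_text(
        json.dumps({"preset": preset, "seed": seed,
                    "n_species": p["n_species"],
                    "survey_rows": len(survey)}, indent=2) + "\n"
    )
    return paths
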