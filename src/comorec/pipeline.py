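"""End-to-end pipeline orchestration.

Runs the full discovery workflow — synthesize (or load) claims, split
80/20, build the incidence matrix, fit the Jaccard similarity model,
extract the top-K diseases for the query and apply the gynecologic
exclusion, evaluate precision/recall on the held-out split, build the
case-control cohort, and fit the crude and adjusted weighted logistic
models — writing every artifact plus a manifest (config, seed, stage row
counts) sufficient to reproduce the run byte-identically.

Every random draw flows from one root seed through named per-stage
substreams, so changing one stage's parameters does not perturb the
randomness of another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import recommender as rec_mod
from . import stats as stats_mod
from .claims import (
    GYNECOLOGIC_RANGES,
    ClaimsDataset,
    CodeRange,
    read_claims,
    write_claims,
)
from .presets import default_population_spec
from .synth import generate_population, population_spec_from_dict

log = logging.getLogger(__name__)

#: Per-stage substream labels hashed off the root seed.
_STAGES = ("synth", "split", "evaluate", "cohort")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic independent seed (< 2^31) for a named pipeline stage."""
    ss = np.random.SeedSequence([root_seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the study settings."""

    seed: int = 0
    n_patients: int = 50_000
    input_claims: str | None = None  # CSV path; None -> synthesize
    synth_spec: str | None = None  # YAML PopulationSpec; None -> preset
    query: str = "N80"
    train_fraction: float = 0.8
    top_k: int = 30
    n_rec: int = 30
    exclusion_ranges: tuple[str, ...] = tuple(
        str(r) for r in GYNECOLOGIC_RANGES
    )
    exclude_before_ranking: bool = False
    catalogue: str | None = None  # YAML disease catalogue; None -> bundled
    level: str = "category"
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.exclusion_ranges, list):
            cfg.exclusion_ranges = tuple(cfg.exclusion_ranges)
        return cfg

    def parsed_exclusions(self) -> tuple[CodeRange, ...]:
        return tuple(CodeRange.parse(r) for r in self.exclusion_ranges)


def _load_or_synthesize(config: RunConfig) -> ClaimsDataset:
    if config.input_claims:
        return read_claims(config.input_claims)
    if config.synth_spec:
        with open(config.synth_spec) as fh:
            spec = population_spec_from_dict(yaml.safe_load(fh))
        spec.n_patients = config.n_patients
    else:
        spec = default_population_spec(config.n_patients)
    return generate_population(spec, seed=stage_seed(config.seed, "synth"))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write artifacts; returns the run directory."""
    exclusions = config.parsed_exclusions()  # fail fast on bad ranges
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    dataset = _load_or_synthesize(config)
    counts["input_records"] = len(dataset)
    write_claims(dataset, out / "claims.csv")

    train, test = rec_mod.train_test_split(
        dataset, config.train_fraction, stage_seed(config.seed, "split")
    )
    counts["train_records"] = len(train)
    counts["test_records"] = len(test)

    incidence = rec_mod.build_incidence(train, code_level="category")
    counts["train_patients_with_dx"] = len(incidence.patient_index)
    counts["categories"] = len(incidence.category_index)
    model = rec_mod.jaccard_similarity(incidence)
    sim_df = pd.DataFrame(
        model.sim, index=model.category_index, columns=model.category_index
    )
    sim_df.to_csv(out / "similarity_matrix.csv", float_format="%.6f")

    top = rec_mod.recommend(model, config.query, config.top_k)
    pd.DataFrame(top.ranked, columns=["category", "similarity"]).to_csv(
        out / f"top_{config.top_k}.csv", index=False, float_format="%.6f"
    )
    survivors = rec_mod.recommend(
        model,
        config.query,
        config.top_k,
        exclusions,
        exclude_before_ranking=config.exclude_before_ranking,
    )
    pd.DataFrame(survivors.ranked, columns=["category", "similarity"]).to_csv(
        out / "candidates_after_exclusion.csv", index=False, float_format="%.6f"
    )
    counts["top_k"] = len(top.ranked)
    counts["candidates_after_exclusion"] = len(survivors.ranked)

    validation = rec_mod.evaluate_rs(
        model, test, config.n_rec, seed=stage_seed(config.seed, "evaluate")
    )
    with open(out / "rs_validation.json", "w") as fh:
        json.dump(dataclasses.asdict(validation), fh, indent=2)

    catalogue = cohort_mod.load_catalogue(config.catalogue)
    endo_def = catalogue.pop("endometriosis")
    candidates = list(catalogue.values())
    if config.level == "full":
        candidates = [
            d
            for defn in candidates
            for d in cohort_mod.expand_to_full_codes(dataset, defn)
        ]
    cohort = cohort_mod.build_cohort(dataset, endo_def, candidates)
    counts["cohort_cases"] = cohort.n_cases
    counts["cohort_controls"] = cohort.n_controls
    counts["dropped_untreated_n80"] = cohort.n_dropped_untreated
    cohort.data.to_csv(out / "cohort.csv", index=False)

    cohort_mod.characteristics_table(cohort).to_csv(
        out / "table1_characteristics.csv", index=False, float_format="%.4g"
    )
    results = stats_mod.run_confirmation(cohort, level=config.level)
    stats_mod.association_table(results).to_csv(
        out / ("table3_full_codes.csv" if config.level == "full" else "table2_category.csv"),
        index=False,
        float_format="%.4g",
    )

    manifest = {
        "config": {
            **dataclasses.asdict(config),
            "exclusion_ranges": list(config.exclusion_ranges),
        },
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "row_counts": counts,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run_pipeline: wrote %d artifacts to %s", len(manifest["artifacts"]), out)
    return out
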