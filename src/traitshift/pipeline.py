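"""End-to-end orchestration: data -> shift models -> PCA -> correlations.

A run is fully determined by a :class:`RunConfig` and a master seed.  Stage
seeds are derived from the master seed through a fixed counter scheme
(``SeedSequence((master, counter))``), so adding a stage never perturbs the
random streams of earlier stages, and re-running with the same config and
seed reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import correlations as corrmod
from . import data as datamod
from . import pca as pcamod
from . import shifts as shiftmod
from .data import TRAIT_NAMES, complete_cases, pair_stages, transform_and_standardize
from .mcmc import RHAT_THRESHOLD, MCMCConfig
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

# fixed stage counters for seed derivation
_SEED_COUNTERS = {
    "synth": 0,
    "shifts": 100,  # + 10 * trait index + variant index
    "pca": 200,  # + stage index
    "correlations": 300,  # + 10 * pair index + stage index
    "regressions": 400,  # + pair index
}

PCA_STAGES = ("adults", "seedlings", "combined")
_PCA_SCOPE = {
    "adults": "adults_only",
    "seedlings": "seedlings_only",
    "combined": "pooled_stages",
}


def derive_seed(master_seed: int, stage: str, offset: int = 0) -> int:
    """Per-stage seed: SeedSequence((master, counter)) folded below 2^31."""
    counter = _SEED_COUNTERS[stage] + offset
    return int(np.random.SeedSequence((int(master_seed), counter)).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything that determines a pipeline run (besides the master seed)."""

    synthetic: bool = True
    input_path: str | None = None
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    shift_traits: tuple[str, ...] = TRAIT_NAMES
    pca_k: int = 2
    pca_kaiser: bool = False
    pca_stages: tuple[str, ...] = PCA_STAGES
    combined_exclude: tuple[str, ...] = ("DA_pit",)
    correlation_pairs: tuple[tuple[str, str], ...] = corrmod.CANONICAL_PAIRS
    similarity_threshold: float = corrmod.SIMILARITY_THRESHOLD
    force_regressions: bool = False
    out_dir: str = "traitshift_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.mcmc.validate()
        if self.synthetic:
            self.synthetic_config.validate()
        elif not self.input_path:
            raise ValueError("input_path is required when synthetic is false")
        unknown = set(self.shift_traits) - set(TRAIT_NAMES)
        if unknown:
            raise ValueError(f"unknown shift traits: {sorted(unknown)}")
        for s in self.pca_stages:
            if s not in PCA_STAGES:
                raise ValueError(f"pca stage must be one of {PCA_STAGES}, got {s!r}")
        if self.pca_k < 1:
            raise ValueError("pca_k must be >= 1")
        if self.similarity_threshold < 0:
            raise ValueError("similarity_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "mcmc" in kwargs and isinstance(kwargs["mcmc"], dict):
            kwargs["mcmc"] = MCMCConfig(**kwargs["mcmc"])
        if "synthetic_config" in kwargs and isinstance(kwargs["synthetic_config"], dict):
            sc = dict(kwargs["synthetic_config"])
            if "trait_shifts" in sc and isinstance(sc["trait_shifts"], dict):
                from .synthetic import TraitShift

                sc["trait_shifts"] = {
                    t: TraitShift(tuple(v["alpha"]), v.get("beta_deciduous", 0.0),
                                  v.get("beta_liana", 0.0), v.get("sd", 0.75))
                    if isinstance(v, dict) else v
                    for t, v in sc["trait_shifts"].items()
                }
            if "loadings_true" in sc and isinstance(sc["loadings_true"], dict):
                sc["loadings_true"] = {t: tuple(v) for t, v in sc["loadings_true"].items()}
            kwargs["synthetic_config"] = SyntheticConfig(**sc)
        for key in ("shift_traits", "pca_stages", "combined_exclude"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "correlation_pairs" in kwargs:
            kwargs["correlation_pairs"] = tuple(tuple(p) for p in kwargs["correlation_pairs"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return {k: convert(v) for k, v in dataclasses.asdict(self).items()}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=None)


class ConvergenceLog:
    """Collects R-hat values from every fitted model in a run."""

    def __init__(self) -> None:
        self.rows: list[dict[str, object]] = []

    def add(self, analysis: str, names: Sequence[str], rhats: Sequence[float]) -> None:
        for name, rhat in zip(names, rhats):
            self.rows.append({"analysis": analysis, "parameter": name, "rhat": float(rhat)})

    def add_summaries(self, analysis: str, summaries) -> None:
        self.add(analysis, [s.name for s in summaries], [s.rhat for s in summaries])


def convergence_report(log: ConvergenceLog) -> pd.DataFrame:
    """One row per parameter with R-hat and a pass flag at the 1.1 threshold."""
    if not log.rows:
        raise ValueError("no fitted models to report on")
    df = pd.DataFrame(log.rows)
    df["pass"] = df["rhat"] < RHAT_THRESHOLD
    return df


def _load_table(config: RunConfig, seed: int, out: Path):
    if config.synthetic:
        sc = dataclasses.replace(config.synthetic_config, seed=derive_seed(seed, "synth"))
        table, truth = generate_dataset(sc)
        data_dir = out / "data"
        data_dir.mkdir(parents=True, exist_ok=True)
        datamod.write_trait_table(table, data_dir / "synthetic_traits.csv")
        truth.to_json(data_dir / "ground_truth.json")
        return table
    return datamod.read_trait_table(config.input_path)


def run_pipeline(config: RunConfig, seed: int, out_dir: str | Path | None = None) -> Path:
    """Execute the full analysis and write per-stage TSV/JSON results.

    Returns the run directory.  Any stage hard error propagates after being
    logged with the stage name.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("traitshift")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    conv = ConvergenceLog()
    bundle: dict[str, object] = {"seed": int(seed)}

    try:
        stage_name = "data"
        table = _load_table(config, seed, out)
        pooled = transform_and_standardize(table, scope="pooled_stages")

        stage_name = "shifts"
        shift_rows = []
        letter_rows = []
        overall_fits: dict[str, shiftmod.ShiftModelResult] = {}
        for ti, trait in enumerate(config.shift_traits):
            shift_data = pair_stages(pooled, trait)
            for vi, variant in enumerate(shiftmod.MODEL_VARIANTS):
                cfg = config.mcmc.with_seed(derive_seed(seed, "shifts", 10 * ti + vi))
                if variant == "overall":
                    res = shiftmod.fit_overall_shift(shift_data, cfg)
                    overall_fits[trait] = res
                elif variant == "site":
                    res = shiftmod.fit_site_shift(shift_data, cfg)
                else:
                    res = shiftmod.fit_full_shift(shift_data, cfg)
                shift_rows.append(res.to_frame())
                conv.add_summaries(f"shift:{trait}:{variant}", res.summaries())
                for site, letters in res.letters.items():
                    letter_rows.append(
                        {"trait": trait, "model": variant, "site": site, "letters": letters}
                    )
        if shift_rows:
            shift_df = pd.concat(shift_rows, ignore_index=True)
            _write_tsv(shift_df, out / "shifts" / "results.tsv")
            if letter_rows:
                _write_tsv(pd.DataFrame(letter_rows), out / "shifts" / "site_letters.tsv")
            bundle["shifts"] = shift_df.to_dict(orient="records")

        stage_name = "pca"
        pca_bundle = {}
        for si, stage in enumerate(config.pca_stages):
            scope = _PCA_SCOPE[stage]
            std = transform_and_standardize(table, scope=scope)
            traits = [t for t in std.trait_names if not (
                stage == "combined" and t in config.combined_exclude)]
            cc = complete_cases(std, traits, stage_filter=scope)
            cfg = config.mcmc.with_seed(derive_seed(seed, "pca", si))
            res = pcamod.fit_bayes_pca(cc, config.pca_k, cfg, kaiser=config.pca_kaiser)
            _write_tsv(res.loadings_frame(), out / "pca" / f"{stage}_loadings.tsv")
            _write_tsv(res.varexp_frame(), out / "pca" / f"{stage}_varexp.tsv")
            _write_tsv(res.scores_frame(cc.row_index), out / "pca" / f"{stage}_scores.tsv")
            conv.add(
                f"pca:{stage}",
                [f"varexp[{j+1}]" for j in range(res.k)],
                res.rhat_varexp,
            )
            pca_bundle[stage] = {
                "n_populations": res.n_populations,
                "varexp_median": res.varexp_median.tolist(),
                "varexp_ci_low": res.varexp_ci_low.tolist(),
                "varexp_ci_high": res.varexp_ci_high.tolist(),
            }
        bundle["pca"] = pca_bundle

        stage_name = "correlations"
        corr_results: dict[tuple[str, str, str], corrmod.CorrelationResult] = {}
        corr_rows = []
        # correlations and regressions use the pooled standardization by contract
        stage_mask = {
            "seedling": np.array([r[2] == "seedling" for r in pooled.row_index]),
            "adult": np.array([r[2] == "adult" for r in pooled.row_index]),
        }
        for pi, (a, b) in enumerate(config.correlation_pairs):
            for sj, stage in enumerate(("seedling", "adult")):
                mask = stage_mask[stage]
                x = pooled.column(a)[mask]
                y = pooled.column(b)[mask]
                cfg = config.mcmc.with_seed(derive_seed(seed, "correlations", 10 * pi + sj))
                res = corrmod.fit_correlation(x, y, cfg, trait_x=a, trait_y=b, stage=stage)
                corr_results[(a, b, stage)] = res
                corr_rows.append(res.as_dict())
                conv.add(f"correlation:{a}-{b}:{stage}", ["rho"], [res.rho.rhat])
        if corr_rows:
            _write_tsv(pd.DataFrame(corr_rows), out / "correlations" / "correlations.tsv")
        bundle["correlations"] = corr_rows

        stage_name = "regressions"
        reg_frames = []
        reg_bundle = []
        for pi, (a, b) in enumerate(config.correlation_pairs):
            rs = corr_results[(a, b, "seedling")]
            ra = corr_results[(a, b, "adult")]
            if not (config.force_regressions or corrmod.correlations_similar(
                    rs, ra, config.similarity_threshold)):
                logger.info("skipping regression contrast for %s-%s: stage correlations differ", a, b)
                continue
            dep = corrmod.choose_dependent_variable((a, b), overall_fits)
            indep = b if dep == a else a
            cfg = config.mcmc.with_seed(derive_seed(seed, "regressions", pi))
            xy = {}
            for stage in ("seedling", "adult"):
                mask = stage_mask[stage]
                xy[stage] = (pooled.column(indep)[mask], pooled.column(dep)[mask])
            contrast = corrmod.compare_stage_regressions(
                xy["seedling"], xy["adult"], cfg, dependent=dep, independent=indep
            )
            reg_frames.append(contrast.to_frame())
            conv.add_summaries(
                f"regression:{dep}~{indep}",
                [
                    contrast.intercept_seedling, contrast.slope_seedling,
                    contrast.intercept_adult, contrast.slope_adult,
                    contrast.intercept_diff, contrast.slope_diff,
                ],
            )
            reg_bundle.append(
                {
                    "dependent": dep,
                    "independent": indep,
                    "intercept_diff_mean": contrast.intercept_diff.mean,
                    "slope_diff_mean": contrast.slope_diff.mean,
                    "n_seedling": contrast.n_seedling,
                    "n_adult": contrast.n_adult,
                }
            )
        if reg_frames:
            _write_tsv(pd.concat(reg_frames, ignore_index=True),
                       out / "correlations" / "regressions.tsv")
        bundle["regressions"] = reg_bundle

        stage_name = "report"
        report = convergence_report(conv)
        _write_tsv(report, out / "convergence.tsv")
        bundle["convergence_pass"] = bool(report["pass"].all())
        bundle["max_rhat"] = float(report["rhat"].max())
        if not bundle["convergence_pass"]:
            failing = report.loc[~report["pass"], ["analysis", "parameter"]]
            logger.warning("R-hat >= %.2f for: %s", RHAT_THRESHOLD, failing.to_dict("records"))
        (out / "results.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
        (out / "resolved_config.yaml").write_text(
            yaml.safe_dump({"seed": int(seed), **config.to_dict()}, sort_keys=True)
        )
    except Exception:
        logger.exception("pipeline stage %r failed", stage_name)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
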