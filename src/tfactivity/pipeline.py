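"""End-to-end orchestration: simulate -> diffexpr -> infer -> coherence.

A run is fully described by a YAML config (versioned schema, unknown keys
rejected) plus a mandatory seed; a rerun with an identical config reproduces
every output draw-for-draw.  Each stage communicates with the next only
through the declared file formats; a manifest records config hash, seed and
tool version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, diffexpr
from .coherence import CoherenceConfig, coherence_table
from .inference import (
    ModelHyperparameters,
    TFActivityPosterior,
    activity_profile,
    build_connectivity,
    infer_tf_activities,
)
from .io import (
    config_hash,
    read_category_table,
    read_expression_table,
    read_regulon_table,
    write_table,
)
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("tfactivity")

_SCHEMA_VERSION = 1

_TOP_KEYS = {
    "schema_version", "seed", "out_dir", "simulate", "expression", "regulon",
    "categories", "diffexpr", "model", "coherence", "strip_genes",
}


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int
    out_dir: Path
    simulate: GeneratorConfig | None = None
    expression_paths: dict[str, Path] = field(default_factory=dict)
    regulon_path: Path | None = None
    categories_path: Path | None = None
    up_threshold: float = 2.0
    down_threshold: float = 0.5
    model: ModelHyperparameters = ModelHyperparameters()
    coherence: CoherenceConfig = CoherenceConfig()
    strip_genes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["expression_paths"] = {k: str(v) for k, v in self.expression_paths.items()}
        d["regulon_path"] = str(self.regulon_path) if self.regulon_path else None
        d["categories_path"] = str(self.categories_path) if self.categories_path else None
        return d


def _subconfig(raw: dict, key: str, cls, extra: dict | None = None):
    block = dict(raw.get(key) or {})
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{key}': {sorted(unknown)}")
    if key == "simulate" and "shape_pairs" in block:
        raise ConfigError("shape_pairs cannot be set from YAML; use the API")
    block.update(extra or {})
    return cls(**block)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; all checks happen up front."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    if raw.get("schema_version", _SCHEMA_VERSION) != _SCHEMA_VERSION:
        raise ConfigError(f"{path}: unsupported schema_version")
    if "seed" not in raw:
        raise ConfigError(f"{path}: seed is mandatory")
    seed = int(raw["seed"])
    out_dir = Path(raw.get("out_dir", "results/run"))

    simulate = None
    if "simulate" in raw:
        simulate = _subconfig(raw, "simulate", GeneratorConfig, extra={"seed": seed})

    expr_block = raw.get("expression") or {}
    expression_paths = {str(k): Path(v) for k, v in expr_block.items()}
    regulon_path = Path(raw["regulon"]) if raw.get("regulon") else None
    categories_path = Path(raw["categories"]) if raw.get("categories") else None

    if simulate is None:
        if not expression_paths:
            raise ConfigError(f"{path}: need an 'expression' mapping or a 'simulate' block")
        if regulon_path is None:
            raise ConfigError(f"{path}: need a 'regulon' path or a 'simulate' block")
        missing = [
            str(p)
            for p in [*expression_paths.values(), regulon_path, categories_path]
            if p is not None and not p.exists()
        ]
        if missing:
            raise ConfigError(f"{path}: referenced files do not exist: {missing}")

    de = dict(raw.get("diffexpr") or {})
    unknown = set(de) - {"up_threshold", "down_threshold"}
    if unknown:
        raise ConfigError(f"{path}: unknown keys in 'diffexpr': {sorted(unknown)}")

    model = _subconfig(raw, "model", ModelHyperparameters, extra={"seed": seed})
    coh = _subconfig(raw, "coherence", CoherenceConfig, extra={"seed": seed})

    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        simulate=simulate,
        expression_paths=expression_paths,
        regulon_path=regulon_path,
        categories_path=categories_path,
        up_threshold=float(de.get("up_threshold", 2.0)),
        down_threshold=float(de.get("down_threshold", 0.5)),
        model=model,
        coherence=coh,
        strip_genes=tuple(raw.get("strip_genes") or ()),
    )


def save_posterior(post: TFActivityPosterior, out_dir: str | Path, seed: int | None = None) -> None:
    """Persist a posterior: activities.tsv (+ flags), diagnostics.tsv, draws.npz."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tf in post.tf_ids:
        prof = activity_profile(post, tf)
        for _, r in prof.iterrows():
            rows.append(
                {"tf": tf, "minute": float(r["minute"]), "mean": float(r["mean"]),
                 "lo95": float(r["lo95"]), "hi95": float(r["hi95"]), "flag": r["flag"]}
            )
    write_table(rows, out / "activities.tsv", seed=seed)
    diag = [
        {"tf": tf, "rhat": float(post.rhat[m]), "flag": post.flags.get(tf, "")}
        for m, tf in enumerate(post.tf_ids)
    ]
    write_table(diag, out / "diagnostics.tsv", seed=seed)
    np.savez_compressed(
        out / "draws.npz",
        draws=post.draws,
        draws_raw=post.draws_raw,
        mean=post.mean,
        lower=post.lower,
        upper=post.upper,
        rhat=post.rhat,
        tf_ids=np.array(post.tf_ids),
        timepoints=np.array(post.timepoints_min),
        flagged=np.array(sorted(post.flags), dtype=object),
    )


def load_posterior(in_dir: str | Path) -> TFActivityPosterior:
    """Load a posterior saved by :func:`save_posterior`."""
    data = np.load(Path(in_dir) / "draws.npz", allow_pickle=True)
    tf_ids = tuple(str(t) for t in data["tf_ids"])
    return TFActivityPosterior(
        tf_ids=tf_ids,
        timepoints_min=tuple(float(t) for t in data["timepoints"]),
        mean=data["mean"],
        lower=data["lower"],
        upper=data["upper"],
        draws=data["draws"],
        draws_raw=data["draws_raw"],
        rhat=data["rhat"],
        flags={str(t): "uninformed" for t in data["flagged"]},
    )


def _write_expression(expr, path: Path) -> None:
    rows = []
    for i, g in enumerate(expr.gene_ids):
        row = {"gene": g}
        for j, t in enumerate(expr.timepoints_min):
            v = expr.values[i, j]
            row[format(t, "g")] = float(v)
        rows.append(row)
    write_table(rows, path)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages, writing all outputs under ``out_dir``.

    Any stage failure aborts with the stage name and offending input in the
    error message.  Collected warnings (dropped TFs, non-convergence,
    omitted coherence points) land in ``warnings.tsv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected: list[dict] = []
    stage = "setup"

    def _log(msg: str, t0: float) -> None:
        logger.info("stage=%s seed=%d wall=%.2fs %s", stage, config.seed, time.time() - t0, msg)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            if config.simulate is not None:
                stage = "simulate"
                t0 = time.time()
                exprs, network, truth = generate_dataset(config.simulate)
                for label, expr in exprs.items():
                    _write_expression(expr, out / f"expr{label}.tsv")
                reg_rows = [
                    {"tf": tf, "gene": g,
                     "sign": {1: "+", -1: "-", None: "?"}[s]}
                    for (tf, g), s in sorted(network.edges.items())
                ]
                write_table(reg_rows, out / "regulon.tsv", seed=config.seed)
                truth_rows = [
                    {"condition": cond, "tf": tf, "minute": float(t), "activity": float(a)}
                    for cond, C in sorted(truth.activities.items())
                    for m, tf in enumerate(truth.tf_ids)
                    for t, a in zip(config.simulate.timepoints, C[m])
                ]
                write_table(truth_rows, out / "truth.tsv", seed=config.seed)
                expression = exprs
                _log(f"simulated {len(exprs)} conditions", t0)
            else:
                stage = "read-inputs"
                t0 = time.time()
                expression = {
                    label: read_expression_table(p, condition_label=label)
                    for label, p in config.expression_paths.items()
                }
                network = read_regulon_table(config.regulon_path)
                _log(f"read {len(expression)} expression tables", t0)

            categories = (
                read_category_table(config.categories_path)
                if config.categories_path
                else None
            )

            stage = "diffexpr"
            t0 = time.time()
            for label, expr in sorted(expression.items()):
                calls = diffexpr.classify_regulation(
                    expr, config.up_threshold, config.down_threshold
                )
                write_table(
                    calls.to_frame().to_dict("records"),
                    out / f"calls_{label}.tsv",
                    seed=config.seed,
                )
                frac_rows = [
                    {"minute": t, "fraction_changed": diffexpr.fraction_changed(calls, t)}
                    for t in calls.timepoints_min
                ]
                write_table(frac_rows, out / f"fractions_{label}.tsv", seed=config.seed)
                if categories is not None:
                    cat_rows = []
                    for t in calls.timepoints_min:
                        for s in diffexpr.category_summary(calls, categories, t):
                            row = dataclasses.asdict(s)
                            row = {"minute": t, **row}
                            cat_rows.append(row)
                    write_table(cat_rows, out / f"categories_{label}.tsv", seed=config.seed)
                if config.strip_genes:
                    strips, not_found = diffexpr.time_strip(expr, list(config.strip_genes))
                    rows = [
                        {"gene": g, **{format(t, "g"): strips.loc[g, t] for t in strips.columns}}
                        for g in strips.index
                    ]
                    write_table(rows, out / f"strips_{label}.tsv", seed=config.seed)
                    for g in not_found:
                        collected.append({"stage": "diffexpr", "message": f"strip gene not found: {g}"})
            _log("wrote regulation calls and summaries", t0)

            stage = "infer-tfa"
            posteriors: dict[str, TFActivityPosterior] = {}
            for k, (label, expr) in enumerate(sorted(expression.items())):
                t0 = time.time()
                conn = build_connectivity(network, expr)
                for tf in conn.dropped_tfs:
                    collected.append(
                        {"stage": "infer-tfa", "message": f"{label}: TF {tf} dropped (no targets in matrix)"}
                    )
                hp = dataclasses.replace(config.model, seed=config.seed + k)
                post = infer_tf_activities(expr, conn, hp)
                posteriors[label] = post
                save_posterior(post, out / f"posterior_{label}", seed=config.seed)
                _log(f"inferred activities for condition {label}", t0)

            if len(posteriors) >= 2:
                stage = "coherence"
                t0 = time.time()
                labels = sorted(posteriors)
                points = coherence_table(
                    posteriors[labels[0]], posteriors[labels[1]], config.coherence
                )
                write_table(points, out / "coherence.tsv", seed=config.seed)
                for p in points:
                    if p.omitted:
                        collected.append(
                            {"stage": "coherence",
                             "message": f"TF {p.tf_id} omitted (|rho| CI half-width > 0.15)"}
                        )
                _log(f"coherence over {len(points)} TFs", t0)

            for w in caught:
                collected.append({"stage": stage, "message": str(w.message)})
    except (ConfigError, PipelineError):
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    write_table(collected, out / "warnings.tsv", seed=config.seed)
    manifest = {
        "tool": "tfactivity",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(json.dumps(config.as_dict(), sort_keys=True, default=str)),
        "stages": ["simulate"] * (config.simulate is not None)
        + ["diffexpr", "infer-tfa"]
        + ["coherence"] * (len(config.expression_paths) >= 2 or config.simulate is not None),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
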