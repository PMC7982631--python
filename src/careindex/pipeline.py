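"""End-to-end orchestration: read or generate a panel, compute indices,
fit and score the QCI model, and emit disparity and decomposition reports.

A run is driven by one :class:`PipelineConfig` (loadable from YAML) and
writes a fixed set of artifacts plus a manifest.  Every output file carries
the config hash in a provenance header; reruns with an identical config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import decomposition as dec
from . import disparity, io, qci
from .errors import ConfigError, PipelineStageError
from .indices import index_table
from .synthetic import SyntheticConfig, generate_panel

log = logging.getLogger("careindex")

OUTPUT_FILES = [
    "indices.csv", "qci_model.txt", "qci_scores.csv", "qci_aggregates.csv",
    "gdr.csv", "scatter_pairs.csv", "decomposition.csv", "exclusions.csv",
]


@dataclass
class PipelineConfig:
    out_dir: str = "careindex_run"
    synthetic: bool = True
    synthetic_config: dict = field(default_factory=dict)
    burden_path: str | None = None
    population_path: str | None = None
    metric: str = "count"
    ref_year: int | None = None
    cur_year: int | None = None
    seed: int = 0
    log_level: str = "INFO"
    report_decimals: int = 2

    def validate(self) -> None:
        if self.synthetic and self.burden_path:
            raise ConfigError("exactly one of synthetic or burden_path may be set")
        if not self.synthetic and not self.burden_path:
            raise ConfigError("either synthetic: true or a burden_path is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Hash of the analysis-relevant config: excludes where outputs land
        (out_dir) and how chatty the run is (log_level), so reruns of the
        same analysis carry the same provenance wherever they are written."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc
            log.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("load")
def _load(config: PipelineConfig):
    if config.synthetic:
        syn = SyntheticConfig(**{**config.synthetic_config, "seed": config.seed})
        cells, pops, truth = generate_panel(syn)
        return cells, pops, truth
    cells = io.read_gbd_csv(config.burden_path)
    pops = (io.read_table(config.population_path)
            if config.population_path else None)
    return cells, pops, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Artifacts written to ``config.out_dir``:

    indices.csv, qci_model.txt, qci_scores.csv, qci_aggregates.csv, gdr.csv,
    scatter_pairs.csv, decomposition.csv, exclusions.csv, manifest.json.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.hash(), "seed": config.seed}

    cells, pops, truth = _load(config)

    panels, pivot_excl = _stage("pivot")(io.pivot_panel)(cells, config.metric)
    if panels.empty:
        reasons = pivot_excl["reason"].value_counts().to_dict()
        raise PipelineStageError(
            "pivot", ConfigError(f"no complete strata; exclusion reasons: {reasons}"))

    vectors = _stage("indices")(index_table)(panels)
    model, _ = _stage("fit")(qci.fit_qci_from_panels)(panels)
    scores, score_audit = _stage("score")(qci.score_qci)(model, vectors)

    aggregates = _stage("aggregate")(
        lambda: pd.concat(
            [qci.aggregate_qci(model, panels, lvl).assign(level=lvl)
             for lvl in qci.AGGREGATION_LEVELS],
            ignore_index=True)
    )()

    gdr, gdr_excl = _stage("gdr")(disparity.gdr_table)(scores)
    pairs = _stage("scatter")(disparity.scatter_pairs)(gdr)

    if pops is not None:
        years = sorted(cells["year"].unique())
        ref_year = config.ref_year if config.ref_year is not None else years[0]
        cur_year = config.cur_year if config.cur_year is not None else years[-1]
        decomp, decomp_excl = _stage("decompose")(dec.decompose_panel)(
            cells, pops, ref_year, cur_year, group_by=("location",))
    else:
        decomp = pd.DataFrame(columns=dec.RESULT_COLUMNS)
        decomp_excl = pd.DataFrame(columns=["group", "sex", "reason"])

    exclusions = pd.concat(
        [pivot_excl.assign(stage="pivot"),
         score_audit.assign(stage="score"),
         gdr_excl.assign(stage="gdr"),
         decomp_excl.assign(stage="decompose")],
        ignore_index=True)

    tables = {
        "indices.csv": vectors,
        "qci_scores.csv": scores,
        "qci_aggregates.csv": aggregates,
        "gdr.csv": gdr,
        "scatter_pairs.csv": pairs,
        "decomposition.csv": decomp,
        "exclusions.csv": exclusions,
    }
    for name, table in tables.items():
        io.write_table(table, out / name, provenance=prov)
    model_text = "\n".join(f"# {k}={v}" for k, v in prov.items()) + "\n" + model.to_text()
    (out / "qci_model.txt").write_text(model_text, encoding="utf-8")

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "outputs": {
            **{name: {"path": str(out / name), "rows": int(len(t))}
               for name, t in tables.items()},
            "qci_model.txt": {"path": str(out / "qci_model.txt"),
                              "variance_explained": model.variance_explained_,
                              "fit_n": model.fit_n_},
        },
        "truth": ({"quality": truth.quality} if truth is not None else None),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report_summary(manifest: dict, decimals: int | None = None) -> str:
    """Human-readable run summary: score extremes, GDR range, decomposition."""
    cfg = manifest["config"]
    decimals = decimals if decimals is not None else cfg.get("report_decimals", 2)
    out = Path(cfg["out_dir"])
    lines = [f"careindex run {manifest['config_hash']}"]

    scores = io.read_table(out / "qci_scores.csv")
    if len(scores):
        lines.append(f"strata scored: {len(scores)}")
        top = scores.nlargest(3, "qci")
        bot = scores.nsmallest(3, "qci")
        fmt = lambda r: (f"  {r.location} {r.year} {r.sex} {r.age_group}: "
                         f"{r.qci:.{decimals}f}")
        lines.append("highest QCI:")
        lines += [fmt(r) for r in top.itertuples()]
        lines.append("lowest QCI:")
        lines += [fmt(r) for r in bot.itertuples()]

    agg = io.read_table(out / "qci_aggregates.csv")
    loc = agg[agg["level"] == "location"] if "level" in agg.columns else agg
    if len(loc):
        lines.append("per-location QCI (28-year compilation):")
        lines += [f"  {r.location}: {r.qci:.{decimals}f}"
                  for r in loc.itertuples()]

    gdr = io.read_table(out / "gdr.csv")
    if len(gdr) and gdr["gdr"].notna().any():
        lines.append(
            f"GDR range: {gdr['gdr'].min():.{decimals}f}"
            f"-{gdr['gdr'].max():.{decimals}f} over {len(gdr)} pairs")

    decomp = io.read_table(out / "decomposition.csv")
    if len(decomp):
        lines.append("incidence-trend decomposition (percent of reference count):")
        rep = dec.format_report(decomp, decimals)
        lines += ["  " + " ".join(f"{k}={v}" for k, v in row.items())
                  for row in rep.to_dict("records")]
    return "\n".join(lines)
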