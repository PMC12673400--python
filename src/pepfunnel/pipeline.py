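"""End-to-end run: train -> generate -> screen -> align -> shortlist.

One global seed governs the whole run (it seeds model initialisation,
shuffling/dropout, and — offset by one — seed-window and length sampling in
generation), so identical (config, seed) runs write byte-identical
artifacts.  Outputs under the run directory:

* ``model.ckpt.npz``   — trained weights + config
* ``pool.fasta``       — the generated pool
* ``candidates.fasta`` — stage-2 funnel survivors
* ``identity.tsv``     — candidates x references percent-identity matrix
* ``shortlist.fasta``  — final similarity-prioritised candidates
* ``report.json``      — funnel counts, per-candidate rows, shortlist ids
* ``manifest.json``    — config echo, seed, package/library versions
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from pepfunnel.generator import GenerationConfig, generate_pool
from pepfunnel.model import BiLSTMNextResidue, ModelConfig, save_checkpoint
from pepfunnel.screen import FunnelReport, FunnelScreen, ScreenConfig
from pepfunnel.seqio import read_fasta, windows_from_records, write_fasta
from pepfunnel.simalign import AlignerParams, IdentityTable, ShortlistConfig, identity_table, shortlist

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report_render"]


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Nested configuration for one reproducible pipeline run."""

    base_fasta: str = ""
    finetune_fasta: str = ""
    out_dir: str = "run"
    model: ModelConfig = field(default_factory=ModelConfig)
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    shortlist: ShortlistConfig = field(default_factory=ShortlistConfig)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (
            ("model", ModelConfig),
            ("generation", GenerationConfig),
            ("screen", ScreenConfig),
            ("shortlist", ShortlistConfig),
            ("aligner", AlignerParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _seeded(cfg: RunConfig) -> RunConfig:
    """Propagate the global seed into the sub-configs (modulo 2**31)."""
    cfg = dataclasses.replace(cfg)
    cfg.model = dataclasses.replace(cfg.model, rng_seed=cfg.rng_seed % (2**31))
    cfg.generation = dataclasses.replace(cfg.generation, rng_seed=(cfg.rng_seed + 1) % (2**31))
    return cfg


def run_pipeline(config: RunConfig) -> FunnelReport:
    """Execute all stages; returns the funnel report (artifacts on disk)."""
    cfg = _seeded(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- corpora ---------------------------------------------------------
    try:
        base = read_fasta(cfg.base_fasta, role="base")
    except Exception as exc:
        raise PipelineError("train", f"cannot read base corpus {cfg.base_fasta!r}: {exc}") from exc
    try:
        refs = read_fasta(cfg.finetune_fasta, role="finetune")
    except Exception as exc:
        raise PipelineError(
            "train",
            f"cannot read fine-tune corpus {cfg.finetune_fasta!r} "
            f"(required for fine-tuning, screening centroid and alignment): {exc}",
        ) from exc

    # --- train -----------------------------------------------------------
    try:
        Xb, yb = windows_from_records(base, cfg.model.window)
        Xf, yf = windows_from_records(refs, cfg.model.window)
        logger.info("training: %d base windows, %d fine-tune windows", len(yb), len(yf))
        model = BiLSTMNextResidue.from_config(cfg.model)
        model.fit(Xb, yb)
        if len(yf):
            model.fine_tune(Xf, yf)
        save_checkpoint(model, out / "model.ckpt.npz")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc

    # --- generate ---------------------------------------------------------
    try:
        corpus = base + refs
        pool = generate_pool(model, corpus, cfg.generation)
        write_fasta(pool, out / "pool.fasta")
        logger.info("generated pool of %d peptides", len(pool))
    except Exception as exc:
        raise PipelineError("generate", str(exc)) from exc

    # --- screen -----------------------------------------------------------
    try:
        screen = FunnelScreen(cfg.screen).fit(refs)
        candidates = screen.transform(pool)
        report = screen.report_
        write_fasta(candidates, out / "candidates.fasta")
        logger.info("funnel: %d -> %d -> %d", report.n_input, report.n_stage1, report.n_stage2)
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    # --- align + shortlist --------------------------------------------------
    try:
        table = identity_table(candidates, refs, cfg.aligner)
        table.values.to_csv(out / "identity.tsv", sep="\t")
        final = shortlist(candidates, table, cfg.shortlist)
        write_fasta(final, out / "shortlist.fasta")
        logger.info("shortlist: %d of %d candidates", len(final), len(candidates))
    except Exception as exc:
        raise PipelineError("align", str(exc)) from exc

    # --- reports ------------------------------------------------------------
    payload = report.to_dict()
    payload["shortlist"] = [r.id for r in final]
    payload["identity_max"] = {rid: float(table.values.loc[rid].max()) for rid in table.rows}
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.rng_seed,
        "versions": _versions(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def _versions() -> dict[str, str]:
    import Bio
    import numpy
    import pandas

    import pepfunnel

    return {
        "pepfunnel": pepfunnel.__version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "biopython": Bio.__version__,
    }


def report_render(report: FunnelReport, table: IdentityTable | None = None) -> str:
    """Human-readable markdown summary of a funnel run."""
    lines = [
        "# Funnel report",
        "",
        f"- pool size: {report.n_input}",
        f"- stage-1 survivors: {report.n_stage1}",
        f"- stage-2 survivors: {report.n_stage2}",
        "",
    ]
    finalists = report.table[report.table["survived_stage2"]]
    if finalists.empty:
        lines.append("No candidates survived the funnel.")
    else:
        lines.append("| id | batch | entropy | GRAVY | instability | composite | distance |")
        lines.append("|---|---|---|---|---|---|---|")
        for row in finalists.itertuples():
            lines.append(
                f"| {row.id} | {row.batch} | {row.entropy:.3f} | {row.gravy:.3f} "
                f"| {row.instability:.2f} | {row.composite_rank} | {row.centroid_distance:.3f} |"
            )
    if table is not None:
        lines += ["", "## Max identity vs references", ""]
        mx = table.values.max(axis=1)
        if mx.empty:
            lines.append("Zero qualifying candidates.")
        for rid, v in mx.items():
            lines.append(f"- {rid}: {v:.2f}%")
    return "\n".join(lines) + "\n"
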