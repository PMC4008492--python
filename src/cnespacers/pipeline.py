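"""End-to-end orchestration: mask -> spacers -> fit -> surrogates -> summary.

`run_analysis` drives the whole chromosome-by-chromosome analysis of an
element track and writes per-chromosome fit tables, a genome summary and
a machine-readable manifest; `run_simulation` drives the duplication-loss
model and writes its snapshot and event tables.  Both are plain library
functions; the command-line interface in :mod:`cnespacers.cli` is a thin
wrapper over them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .powerlaw import FitParams, GenomeSummary, chromosome_report, genome_summary
from .simulator import SimConfig, SimRun, run_model
from .tracks import (
    ElementTrack,
    MaskTrack,
    build_gene_mask,
    read_chrom_sizes,
    read_elements,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "run_simulation", "load_sim_config",
           "FLANK_MODES"]

# masking modes: (flank5, flank3, strand_aware)
FLANK_MODES = {
    "none": None,
    "flank5k2k": (5_000, 2_000),
    "flank10k": (10_000, 10_000),
    "flank100k": (100_000, 100_000),
}


@dataclass
class RunConfig:
    """Settings for one analysis run."""

    elements: str | ElementTrack
    genes: str | ElementTrack | None = None
    chrom_sizes: str | dict | None = None
    mask_mode: str = "none"
    fit_params: FitParams = field(default_factory=FitParams)
    n_surrogates: int = 10
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mask_mode not in FLANK_MODES:
            raise ValueError(
                f"unknown mask mode {self.mask_mode!r}; "
                f"choose from {sorted(FLANK_MODES)}"
            )


def _resolve_track(obj, sizes) -> ElementTrack:
    if isinstance(obj, ElementTrack):
        return obj
    return read_elements(obj, chrom_sizes=sizes)


def run_analysis(config: RunConfig) -> GenomeSummary:
    """Run the full spacer-distribution analysis for every chromosome.

    Applies the configured gene+flank mask (if any), computes spacer
    CCDFs, detects the log-log linear region per chromosome, attaches a
    surrogate bundle per chromosome, and aggregates avg E / avg E-5.
    When ``out_dir`` is set, writes ``per_chromosome.tsv``,
    ``summary.tsv``, ``surrogates.tsv`` and ``manifest.json``.
    """
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    sizes = config.chrom_sizes
    if isinstance(sizes, str):
        sizes = read_chrom_sizes(sizes)
    track = _resolve_track(config.elements, sizes)

    mask: MaskTrack | None = None
    flanks = FLANK_MODES[config.mask_mode]
    if flanks is not None:
        if config.genes is None:
            raise ValueError("masking requested but no gene track given")
        genes = _resolve_track(config.genes, sizes)
        mask = build_gene_mask(genes, flank5=flanks[0], flank3=flanks[1])

    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(track.chromosomes) or 1
    )
    results = []
    for chrom, sub_seed in zip(track.chromosomes, seeds):
        results.append(
            chromosome_report(
                track,
                chrom,
                mask=mask,
                params=config.fit_params,
                n_surrogates=config.n_surrogates,
                seed=int(sub_seed % (2**31)),
            )
        )
    summary = genome_summary(results)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.as_table().to_csv(out / "per_chromosome.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"n_chromosomes": len(results),
              "n_accepted": sum(r.accepted for r in results),
              "avg_E": summary.avgE, "avg_E5": summary.avgE5,
              "mask_mode": config.mask_mode}]
        ).to_csv(out / "summary.tsv", sep="\t", index=False)
        surr_rows = [
            {"chrom": r.chrom, "replicate": i, "E": f.E, "mu": f.mu,
             "r2": f.r2, "accepted": f.accepted}
            for r in results
            for i, f in enumerate(r.surrogate_fits)
        ]
        pd.DataFrame(surr_rows).to_csv(out / "surrogates.tsv", sep="\t", index=False)
        manifest = {
            "tool": "cnespacers", "version": __version__,
            "command": "analyze", "seed": config.seed,
            "mask_mode": config.mask_mode,
            "fit_params": dataclasses.asdict(config.fit_params),
            "n_surrogates": config.n_surrogates,
            "elements": str(config.elements)
            if not isinstance(config.elements, ElementTrack) else "<in-memory>",
            "genes": str(config.genes)
            if config.genes is not None and not isinstance(config.genes, ElementTrack)
            else ("<in-memory>" if config.genes is not None else None),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


# ---------------------------------------------------------------------------
# Simulation driver


_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)} - {"fit_params"}


def load_sim_config(path) -> SimConfig:
    """Read a flat ``key = value`` (or ``key: value``) simulator config file."""
    kwargs: dict = {}
    unknown: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, val = (t.strip() for t in line.split(sep, 1))
                    break
            else:
                raise ValueError(f"unparsable config line: {line!r}")
            if key not in _SIM_KEYS:
                unknown.append(key)
                continue
            target = str(SimConfig.__dataclass_fields__[key].type)
            if "float" in target:
                kwargs[key] = float(val)
            elif "int" in target:
                kwargs[key] = int(val)
            else:
                kwargs[key] = val
    if unknown:
        raise ValueError(f"unknown simulator config keys: {', '.join(sorted(unknown))}")
    return SimConfig(**kwargs)


def run_simulation(
    config: SimConfig | str, out_dir: str | None = None, seed: int | None = None
) -> SimRun:
    """Execute the duplication-loss model and write snapshot/fit/event TSVs."""
    if not isinstance(config, SimConfig):
        config = load_sim_config(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    run = run_model(config)

    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for snap in run.snapshots:
            snap.dist.as_table().to_csv(
                out / f"snapshot_{snap.events:05d}.tsv", sep="\t", index=False
            )
        fits = pd.DataFrame(
            [
                {"events": s.events, "n_markers": s.n_markers, "L": s.L,
                 "E": s.fit.E, "mu": s.fit.mu, "r2": s.fit.r2,
                 "S_lower": s.fit.S_lower, "S_upper": s.fit.S_upper,
                 "accepted": s.fit.accepted}
                for s in run.snapshots
            ]
        )
        fits.to_csv(out / "fits.tsv", sep="\t", index=False)
        pd.DataFrame(run.event_log).to_csv(out / "events.tsv", sep="\t", index=False)
        manifest = {
            "tool": "cnespacers", "version": __version__,
            "command": "simulate",
            "config": {k: v for k, v in dataclasses.asdict(config).items()
                       if k != "fit_params"},
            "fit_params": dataclasses.asdict(config.fit_params),
            "completed": run.completed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run


def plot_ccdf_bundle(dist, surrogates, path, fit=None) -> None:
    """Diagnostic log-log plot: genomic CCDF plus a surrogate bundle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for d in surrogates:
        ax.plot(d.values, d.counts, color="0.7", lw=0.8, zorder=1)
    ax.plot(dist.values, dist.counts, "o", ms=2.5, color="C0", zorder=2)
    if fit is not None and fit.accepted:
        s = np.array([fit.S_lower, fit.S_upper])
        n0 = float(dist.count_ge(fit.S_lower))
        ax.plot(s, n0 * (s / fit.S_lower) ** (-fit.mu), "C3-", lw=1.5,
                label=f"E={fit.E:.2f}, mu={fit.mu:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel("spacer length S (bp)")
    ax.set_ylabel("N(S)")
    ax.set_xscale("log")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
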