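"""Pipeline wiring: profile -> filter -> arrange -> evaluate, with config.

The library entry points here are what the CLI, the test-suite and the
reproduction script all call; a run is fully determined by its
:class:`RunConfig` plus input files, and the config is persisted verbatim into
every run's output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .arrange import (
    Arrangement, apply_arrangement, arrange, arrangement_table,
    junction_report, write_agp,
)
from .evaluate import EvalResult, evaluate_arrangement
from .io import ContigSeq, load_depth, read_contigs, write_contigs
from .profiles import (
    BinnedProfile, GradientDiagnostic, SlopeFit, assess_gradient, bin_coverage,
    filter_short_contigs, fit_slope,
)
from .simulate import TruthTable

log = logging.getLogger("erparrange")

CONFIG_SCHEMA_VERSION = 1

#: fixed per-stage offsets fanned out from the one global seed
_STAGE_OFFSETS = {"genome": 11, "depth": 23, "fragment": 37, "null": 53}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stable, < 2**31)."""
    return (seed * 100_003 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class RunConfig:
    """All tunable knobs of a run; persisted alongside every output."""

    bin_size: int = 1000
    min_fraction: float = 0.01
    slack: float = 0.05
    zero_slope_tolerance: float = 1.0
    ambiguity_r2: float = 0.5
    k_anchor: int = 31
    null_reps: int = 100
    spacer_n: int = 100
    seed: int = 0
    genome_size: int | None = None

    def __post_init__(self):
        for name in ("bin_size", "min_fraction", "slack", "zero_slope_tolerance",
                     "k_anchor", "spacer_n"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_schema_version"] = CONFIG_SCHEMA_VERSION
        return d


@dataclass
class ArrangeOutput:
    """Everything the profile+arrange stages produce for one dataset."""

    profiles: dict[str, BinnedProfile]
    fits: dict[str, SlopeFit]
    kept: list[SlopeFit]
    discarded: list[SlopeFit]
    diagnostic: GradientDiagnostic | None
    arrangement: Arrangement
    pseudo_molecule: ContigSeq
    placements: object  # pandas DataFrame


def profile_and_fit(
    contigs: list[ContigSeq],
    depths: dict[str, np.ndarray],
    bin_size: int = 1000,
) -> tuple[dict[str, BinnedProfile], dict[str, SlopeFit]]:
    """Bin every contig's depth and fit its least-squares slope."""
    profiles, fits = {}, {}
    for c in contigs:
        prof = bin_coverage(depths[c.id], bin_size, contig_id=c.id)
        profiles[c.id] = prof
        fits[c.id] = fit_slope(prof, c.length)
    return profiles, fits


def arrange_contigs(
    contigs: list[ContigSeq],
    depths: dict[str, np.ndarray],
    config: RunConfig | None = None,
) -> ArrangeOutput:
    """Run profile -> filter -> gradient check -> arrange -> pseudo-molecule."""
    cfg = config or RunConfig()
    profiles, fits = profile_and_fit(contigs, depths, cfg.bin_size)
    lengths = {c.id: c.length for c in contigs}
    kept, discarded = filter_short_contigs(
        list(fits.values()), lengths,
        min_fraction=cfg.min_fraction, genome_size=cfg.genome_size,
    )
    for f in discarded:
        profiles[f.contig_id].usable = False
        log.info("discarded short contig %s (%d bp)", f.contig_id, f.length)
    diagnostic = None
    if len(kept) >= 2:
        diagnostic = assess_gradient(
            kept, [profiles[f.contig_id] for f in kept]
        )
        log.info(
            "gradient verdict: %s (ratio %.2f, frac sloped %.2f)",
            diagnostic.verdict, diagnostic.ratio_high_low, diagnostic.frac_sloped,
        )
    arr = arrange(
        kept,
        slack_frac=cfg.slack,
        zero_slope_tol=cfg.zero_slope_tolerance,
        ambiguity_r2=cfg.ambiguity_r2,
    )
    kept_ids = {f.contig_id for f in kept}
    pm, placements = apply_arrangement(
        arr, [c for c in contigs if c.id in kept_ids], spacer_n=cfg.spacer_n
    )
    return ArrangeOutput(
        profiles=profiles, fits=fits, kept=kept, discarded=discarded,
        diagnostic=diagnostic, arrangement=arr, pseudo_molecule=pm,
        placements=placements,
    )


def _diag_dict(d: GradientDiagnostic | None) -> dict | None:
    if d is None:
        return None
    return {
        "ratio_high_low": d.ratio_high_low,
        "frac_sloped": d.frac_sloped,
        "verdict": d.verdict,
        "n_contigs": d.n_contigs,
    }


def _eval_dict(e: EvalResult | None) -> dict | None:
    if e is None:
        return None
    return dataclasses.asdict(e)


def run_pipeline(
    config: RunConfig,
    contigs_path,
    depth_path,
    outdir,
    reference_path=None,
    truth_path=None,
) -> dict:
    """File-based pipeline run; writes all outputs and returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs_path = Path(contigs_path)
    depth_path = Path(depth_path)
    for p, stage in ((contigs_path, "contigs"), (depth_path, "depth")):
        if not p.exists():
            raise FileNotFoundError(f"{stage} file not found: {p}")

    log.info("reading contigs from %s", contigs_path)
    contigs = read_contigs(contigs_path)
    log.info("loading depth from %s", depth_path)
    depths = load_depth(depth_path, contigs)
    out = arrange_contigs(contigs, depths, config)

    # outputs
    arrangement_table(out.arrangement, list(out.fits.values())).to_csv(
        outdir / "arrangement.tsv", sep="\t", index=False
    )
    junction_report(out.arrangement, list(out.fits.values())).to_csv(
        outdir / "junctions.tsv", sep="\t", index=False
    )
    kept_ids = {f.contig_id for f in out.kept}
    kept_contigs = [c for c in contigs if c.id in kept_ids]
    write_contigs([out.pseudo_molecule], outdir / "pseudo_molecule.fasta")
    write_agp(out.arrangement, kept_contigs, outdir / "arrangement.agp",
              spacer_n=config.spacer_n)
    prof_rows = []
    for cid, prof in out.profiles.items():
        half = prof.bin_size / 2
        for mid, depth in zip(prof.bin_mid, prof.bin_depth):
            prof_rows.append((cid, mid - half + 0.5, mid + half + 0.5, depth))
    with open(outdir / "profiles.tsv", "w") as fh:
        fh.write("contig_id\tbin_start\tbin_end\tdepth\n")
        for row in prof_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    evaluation = None
    if reference_path is not None:
        reference = read_contigs(reference_path)[0]
        truth = TruthTable.read_tsv(truth_path) if truth_path else None
        evaluation = evaluate_arrangement(
            out.arrangement, contigs, reference, truth=truth,
            k=config.k_anchor, null_reps=config.null_reps,
            seed=stage_seed(config.seed, "null"), spacer_n=config.spacer_n,
        )
        log.info("coverage rate: %.2f%%", evaluation.coverage_rate)

    report = {
        "version": version_info(),
        "config": config.to_json(),
        "n_contigs": len(contigs),
        "n_kept": len(out.kept),
        "n_discarded": len(out.discarded),
        "discarded_ids": sorted(f.contig_id for f in out.discarded),
        "gradient": _diag_dict(out.diagnostic),
        "arrangement": {
            "shift_index": out.arrangement.shift_index,
            "total_delta": out.arrangement.total_delta,
            "order": [
                {"contig_id": oc.contig_id, "orientation": oc.orientation,
                 "ambiguous": oc.ambiguous}
                for oc in out.arrangement.order
            ],
        },
        "evaluation": _eval_dict(evaluation),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def version_info() -> str:
    """Semantic package version plus config schema version."""
    return f"erparrange {__version__} (config schema {CONFIG_SCHEMA_VERSION})"
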