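"""End-to-end orchestration of the enriched-region caller.

``run_pipeline`` wires the stages together: duplicate filtering, fragment
extension and read-depth profiles, control normalization, mappability
correction, multiscale median decomposition, scale-specific enriched
region calling, cross-scale merging with FDR control, and the pileup
scale spectrum.  ``RunConfig`` bundles every tunable with presets for the
three canonical ER length regimes (broad histone marks, punctate marks,
transcription factors).
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from . import er_calls, multiscale, preprocess, scale_spectrum, sser
from .mappability import MultiMappabilityProfile
from .signal_io import GenomeTable, Read, SignalProfile, write_bedgraph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "PRESETS", "run_pipeline"]

PRESETS: dict[str, dict] = {
    "broad": {"l_start": 1000, "l_end": 16000, "l_pval": 1750},
    "punctate": {"l_start": 100, "l_end": 2000, "l_pval": 1500},
    "tf": {"l_start": 100, "l_end": 200, "l_pval": 200},
}


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables; lengths in bp."""

    l_start: int = 1000
    l_end: int = 16000
    sigma: float = 1.5
    gamma: float = 4.0
    l_c: int = 2000
    l_pval: int = 1750
    q_cutoff: float = 0.05
    fragment_length: int = 200
    mappability_threshold: float = 1.2
    duplicate_cap: int = 1
    bin_length: int = 10_000
    background_window: int = 1_000_000
    preset: str = "custom"

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        params = dict(PRESETS[name])
        params.update(overrides)
        return cls(preset=name, **params)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        params = json.loads(Path(path).read_text())
        params.update(overrides)
        return cls(**params)


@dataclass
class PipelineResult:
    config: RunConfig
    ers: list[er_calls.EnrichedRegion]
    ssers: dict[str, list[sser.SSER]]
    schedule: multiscale.ScaleSchedule
    rho: float
    pileup: dict[str, scale_spectrum.PileupScaleProfile]
    spectrum: scale_spectrum.SpectrumHistogram
    corrected: dict[str, SignalProfile]
    stage_counts: dict[str, int]

    @property
    def all_ssers(self) -> list[sser.SSER]:
        return [s for chrom_ssers in self.ssers.values() for s in chrom_ssers]


def run_pipeline(
    config: RunConfig,
    chip_reads: dict[str, list[Read]],
    control_reads: dict[str, list[Read]],
    genome: GenomeTable,
    mappability: dict[str, MultiMappabilityProfile] | None = None,
    save_bedgraph_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full caller on in-memory reads.

    Without a multi-mappability profile the correction step is skipped:
    a hard error under the broad preset (the correction is load-bearing
    for broad marks fragmented by repeats), a warning otherwise.
    """
    if mappability is None:
        if config.preset == "broad":
            raise ValueError(
                "the broad preset requires a multi-mappability profile; "
                "broad domains fragment without the correction"
            )
        logger.warning("no multi-mappability profile: skipping signal correction")

    chip_reads = {c: preprocess.deduplicate(r, config.duplicate_cap)
                  for c, r in chip_reads.items()}
    control_reads = {c: preprocess.deduplicate(r, config.duplicate_cap)
                     for c, r in control_reads.items()}
    rd_chip = preprocess.build_rd_profile(chip_reads, genome, config.fragment_length)
    rd_control = preprocess.build_rd_profile(control_reads, genome, config.fragment_length)
    chip_idx = preprocess.build_fragment_index(chip_reads, genome, config.fragment_length)
    ctrl_idx = preprocess.build_fragment_index(control_reads, genome, config.fragment_length)

    fit = preprocess.estimate_normalization_factor(
        {c: p.total for c, p in rd_chip.items()},
        {c: p.total for c, p in rd_control.items()},
        config.bin_length,
    )
    logger.info("control normalization factor rho = %.4f over %d bins", fit.rho, fit.n_bins)

    corrected: dict[str, SignalProfile] = {}
    for chrom, profiles in rd_chip.items():
        if mappability is not None:
            mm = mappability[chrom]
            if abs(mm.m_exonic_threshold - config.mappability_threshold) > 1e-12:
                mm = MultiMappabilityProfile(
                    chrom, mm.values, config.mappability_threshold
                )
            corrected[chrom] = preprocess.correct_mappability(
                profiles.total, mm, config.l_c
            )
        else:
            corrected[chrom] = SignalProfile(
                chrom, profiles.total.values.astype("int64")
            )

    schedule = multiscale.make_schedule(config.l_start, config.l_end, config.sigma)
    logger.info("scale schedule: %d windows from %d to %d bp",
                len(schedule), schedule.windows[0], schedule.windows[-1])

    ssers_by_chrom: dict[str, list[sser.SSER]] = {}
    stage_counts = {"candidates": 0, "gamma_kept": 0, "trimmed": 0, "ssers": 0}
    decompositions: dict[str, multiscale.ScaleDecomposition] = {}
    for chrom, _ in genome:
        raw = corrected[chrom]
        bg = sser.fit_background(raw, config.background_window)
        decomp = multiscale.decompose(raw, schedule)
        decompositions[chrom] = decomp
        chrom_ssers, counts = sser.call_ssers(
            decomp, raw, bg, chip_idx[chrom], ctrl_idx[chrom],
            fit.rho, config.l_pval, config.gamma,
        )
        ssers_by_chrom[chrom] = chrom_ssers
        for key in stage_counts:
            stage_counts[key] += counts[key]
        logger.info("%s: %s", chrom, counts)

    all_ssers = [s for chrom_ssers in ssers_by_chrom.values() for s in chrom_ssers]
    ers = er_calls.call_ers(
        all_ssers, corrected, rd_chip, chip_idx, ctrl_idx,
        fit.rho, config.l_pval, config.q_cutoff, mappability,
    )
    stage_counts["merged"] = len(er_calls.merge_ssers(all_ssers))
    stage_counts["final_ers"] = len(ers)

    pileup = scale_spectrum.compute_pileup_scale(all_ssers, genome)
    spectrum = scale_spectrum.spectrum_histogram(pileup, schedule)

    if save_bedgraph_dir is not None:
        out = Path(save_bedgraph_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bedgraph(corrected, out / "corrected.bedgraph")
        for k, window in enumerate(schedule.windows):
            per_scale = {c: decompositions[c].smoothed[k] for c, _ in genome}
            write_bedgraph(per_scale, out / f"scale_{window}.bedgraph")

    return PipelineResult(
        config=config,
        ers=ers,
        ssers=ssers_by_chrom,
        schedule=schedule,
        rho=fit.rho,
        pileup=pileup,
        spectrum=spectrum,
        corrected=corrected,
        stage_counts=stage_counts,
    )
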