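"""Pipeline orchestration: simulate → scan → correlate, pulldown, occupancy.

A :class:`RunConfig` (built directly, from a YAML ``key: value`` file, or by
the command-line layer) names the inputs, parameters and output directory.
:func:`run_pipeline` executes the requested stages, writes versioned
plain-text artifacts, a human-readable log and a machine-readable
``manifest.json`` recording inputs, parameters, the seed and SHA-256
checksums of every output.  Identical configurations produce byte-identical
outputs and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import io as kio
from .clusters import (
    DEFAULT_WINDOWS,
    PeakRegion,
    compare_ranked_halves,
    correlation_curve,
    count_weak_sites,
    cumulative_z,
)
from .motifs import ScanConfig, designate_sites
from .occupancy import occupancy_frame
from .pulldown import run_enrichment
from .simulate import CohortSpec, gen_peak_cohort, gen_pulldown, gen_zscore_table

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    outdir: str = "kbsites_out"
    seed: int = 0
    # inputs (read stages)
    fasta: Optional[str] = None
    zscore_table: Optional[str] = None
    peaks: Optional[str] = None
    peak_format: str = "narrowPeak"
    pulldown_counts: Optional[str] = None
    pulldown_tags: Optional[str] = None
    # scanning
    consensus: str = "GGGRNNYYCC"
    max_mismatches: int = 3
    strong_threshold: float = 6.0
    scan_both_strands: bool = True
    # correlation
    windows: Tuple[int, ...] = DEFAULT_WINDOWS
    report_windows: Tuple[int, ...] = (10, 150, 500)
    log_scores: bool = False
    # occupancy
    concentrations_nm: Tuple[float, ...] = (100.0, 200.0, 250.0)
    kds_nm: Tuple[float, ...] = (27.0, 250.0, 300.0, 1500.0, 3000.0)
    # pulldown
    min_total_count: int = 5
    z_margin: float = 0.5
    n_clusters: Optional[int] = 4
    # simulation
    n_peaks: int = 100
    span_bp: int = 150
    table_entries: int = 200
    n_proteins: int = 50
    n_enriched: int = 5
    effect_size: float = 20.0
    log_level: str = "INFO"

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            consensus=self.consensus,
            max_mismatches=self.max_mismatches,
            strong_threshold=self.strong_threshold,
            scan_both_strands=self.scan_both_strands,
        )

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a plain-text ``key: value`` (YAML) config, with overrides."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must map keys to values")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        for key in ("windows", "report_windows", "concentrations_nm", "kds_nm"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate_windows(self) -> None:
        w = list(self.windows)
        if w != sorted(set(w)) or (w and (w[0] < 10 or w[-1] > 500)):
            raise ValueError("windows must be increasing and within [10, 500]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_regions(config: RunConfig) -> List[PeakRegion]:
    sequences = kio.read_fasta(config.fasta)
    table = kio.read_zscore_table(config.zscore_table)
    calls = kio.read_peaks(config.peaks, format=config.peak_format)
    scan = config.scan_config()
    regions = []
    for call in calls:
        if call.region_id not in sequences:
            raise ValueError(f"peak {call.region_id!r} has no FASTA record")
        seq = sequences[call.region_id]
        center = call.summit if call.summit is not None else len(seq) / 2
        regions.append(
            PeakRegion.from_sequence(
                call.region_id, seq, call.score, table, scan, region_center=center
            )
        )
    return regions


def _stage_simulate(config: RunConfig, outdir: Path, outputs: List[Path]) -> Dict:
    table = gen_zscore_table(config.table_entries, seed=config.seed)
    spec = CohortSpec(n_peaks=config.n_peaks, span_bp=config.span_bp, seed=config.seed)
    peaks, truth = gen_peak_cohort(spec, table, config.scan_config())
    matrix, enriched = gen_pulldown(
        n_proteins=config.n_proteins,
        n_enriched=config.n_enriched,
        effect_size=config.effect_size,
        seed=config.seed,
    )
    table_path = outdir / "zscore_table.tsv"
    fasta_path = outdir / "regions.fa"
    peaks_path = outdir / "peaks.narrowPeak"
    truth_path = outdir / "planted_sites.tsv"
    counts_path = outdir / "pulldown_counts.tsv"
    tags_path = outdir / "pulldown_tags.tsv"
    enriched_path = outdir / "planted_enriched.tsv"
    kio.write_zscore_table(table_path, table)
    kio.write_fasta(fasta_path, {p.region_id: p.sequence for p in peaks})
    calls = [
        kio.PeakCall(p.region_id, p.region_id, 0, len(p.sequence), p.chip_score,
                     ".", int(p.anchor_offset))
        for p in peaks
    ]
    kio.write_peaks(peaks_path, calls, format="narrowPeak")
    kio.write_sites_table(truth_path, {t.region_id: t.planted_sites for t in truth.peaks})
    kio.write_pulldown(counts_path, tags_path, matrix)
    with open(enriched_path, "w") as fh:
        fh.write("protein\n")
        for name in sorted(enriched):
            fh.write(name + "\n")
    outputs.extend(
        [table_path, fasta_path, peaks_path, truth_path, counts_path, tags_path, enriched_path]
    )
    logger.info("simulate: %d peaks, %d table entries, %d proteins",
                len(peaks), len(table), config.n_proteins)
    # downstream stages read the files we just wrote
    config.fasta = str(fasta_path)
    config.zscore_table = str(table_path)
    config.peaks = str(peaks_path)
    config.pulldown_counts = str(counts_path)
    config.pulldown_tags = str(tags_path)
    return {"n_peaks": len(peaks), "table_entries": len(table)}


def _stage_scan(config: RunConfig, outdir: Path, outputs: List[Path]) -> Dict:
    if not config.fasta or not config.zscore_table:
        raise ValueError("scan requires --fasta and --zscore-table inputs")
    sequences = kio.read_fasta(config.fasta)
    table = kio.read_zscore_table(config.zscore_table)
    scan = config.scan_config()
    sites = {name: designate_sites(seq, table, scan) for name, seq in sequences.items()}
    bed_path = outdir / "sites.bed"
    tsv_path = outdir / "sites.tsv"
    kio.write_sites_bed(bed_path, sites)
    kio.write_sites_table(tsv_path, sites)
    outputs.extend([bed_path, tsv_path])
    n_sites = sum(len(v) for v in sites.values())
    logger.info("scan: %d sites designated over %d sequences", n_sites, len(sequences))
    return {"n_sequences": len(sequences), "n_sites": n_sites}


def _stage_correlate(config: RunConfig, outdir: Path, outputs: List[Path]) -> Dict:
    if not (config.fasta and config.zscore_table and config.peaks):
        raise ValueError("correlate requires --fasta, --zscore-table and --peaks inputs")
    config.validate_windows()
    regions = _build_regions(config)
    curve = correlation_curve(regions, config.windows, log_scores=config.log_scores)
    halves = compare_ranked_halves(regions)
    ranked = sorted(regions, key=lambda p: (-p.chip_score, p.region_id))
    top_ids = {p.region_id for p in ranked[: len(ranked) // 2]}
    curve_path = outdir / "correlation_curve.tsv"
    report_path = outdir / "per_peak_report.tsv"
    halves_path = outdir / "ranked_halves.tsv"
    kio.write_curve(curve_path, curve)
    with open(report_path, "w") as fh:
        cz_cols = [f"cumulative_z_{L}" for L in config.report_windows]
        fh.write("region_id\tchip_score\tanchor_offset\t" + "\t".join(cz_cols)
                 + "\tweak_sites\thalf\n")
        for p in sorted(regions, key=lambda p: p.region_id):
            cz = [repr(cumulative_z(p, L)) for L in config.report_windows]
            half = "top" if p.region_id in top_ids else "bottom"
            fh.write(
                f"{p.region_id}\t{p.chip_score!r}\t{p.anchor_offset!r}\t"
                + "\t".join(cz) + f"\t{count_weak_sites(p)}\t{half}\n"
            )
    with open(halves_path, "w") as fh:
        fh.write("mean_top\tmean_bottom\tt_statistic\tp_value\tn_top\tn_bottom\n")
        fh.write(
            f"{halves.mean_top!r}\t{halves.mean_bottom!r}\t{halves.t_statistic!r}\t"
            f"{halves.p_value!r}\t{halves.n_top}\t{halves.n_bottom}\n"
        )
    outputs.extend([curve_path, report_path, halves_path])
    logger.info("correlate: %d peaks, %d windows, ranked-halves p=%.4g",
                len(regions), len(list(config.windows)), halves.p_value)
    return {"n_peaks": len(regions), "p_value": halves.p_value}


def _stage_occupancy(config: RunConfig, outdir: Path, outputs: List[Path]) -> Dict:
    frame = occupancy_frame(config.concentrations_nm, config.kds_nm)
    path = outdir / "occupancy.tsv"
    frame.to_csv(path, sep="\t", float_format="%.6g")
    outputs.append(path)
    logger.info("occupancy: %d x %d grid", *frame.shape)
    return {"grid": list(frame.shape)}


def _stage_pulldown(config: RunConfig, outdir: Path, outputs: List[Path]) -> Dict:
    if not (config.pulldown_counts and config.pulldown_tags):
        raise ValueError("pulldown requires --pulldown-counts and --pulldown-tags inputs")
    matrix = kio.read_pulldown(config.pulldown_counts, config.pulldown_tags)
    result = run_enrichment(
        matrix,
        min_total=config.min_total_count,
        z_margin=config.z_margin,
        n_clusters=config.n_clusters,
        seed=config.seed,
    )
    path = outdir / "pulldown_enrichment.tsv"
    out = result.zscores.copy()
    out.columns = [f"z_{c}" for c in out.columns]
    out.insert(0, "total_count", result.matrix.counts.sum(axis=1))
    out["enrichment_score"] = result.enrichment_score
    out["passed"] = result.passed
    if result.cluster_labels is not None:
        out["cluster"] = result.cluster_labels
    out.to_csv(path, sep="\t", index_label="protein")
    norm_path = outdir / "pulldown_normalized.tsv"
    result.normalized.to_csv(norm_path, sep="\t", index_label="protein")
    outputs.extend([path, norm_path])
    logger.info("pulldown: %d/%d proteins retained, %d enriched",
                result.zscores.shape[0], matrix.counts.shape[0], int(result.passed.sum()))
    return {
        "n_retained": int(result.zscores.shape[0]),
        "n_enriched": int(result.passed.sum()),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "correlate": _stage_correlate,
    "occupancy": _stage_occupancy,
    "pulldown": _stage_pulldown,
}

#: stage order for the `all` subcommand
_ALL = ("simulate", "scan", "correlate", "occupancy", "pulldown")


def run_pipeline(config: RunConfig, stages: Sequence[str] = _ALL) -> int:
    """Execute the requested stages; returns 0 iff all succeed.

    Outputs, a run log and ``manifest.json`` land in ``config.outdir``.  On a
    stage failure the manifest marks the stage as failed and the run as
    partial; already-written outputs are kept.
    """
    for name in stages:
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
    config = dataclasses.replace(config)  # stages rewire input paths; keep caller's copy
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("kbsites")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    outputs: List[Path] = []
    stage_info: Dict[str, Dict] = {}
    status = 0
    try:
        for name in stages:
            try:
                info = _STAGES[name](config, outdir, outputs)
                stage_info[name] = {"status": "ok", **info}
            except Exception as exc:  # noqa: BLE001 — report and mark partial
                logger.error("stage %s failed: %s", name, exc)
                stage_info[name] = {"status": "failed", "error": str(exc)}
                status = 1
                break
    finally:
        root.removeHandler(handler)
        handler.close()
    params = dataclasses.asdict(config)
    # keep manifests location-independent: paths under outdir become basenames
    prefix = str(outdir)
    for key, value in params.items():
        if isinstance(value, str) and value.startswith(prefix):
            params[key] = Path(value).name
    params["outdir"] = "."
    manifest = {
        "tool": "kbsites",
        "seed": config.seed,
        "parameters": params,
        "stages": stage_info,
        "status": "ok" if status == 0 else "partial",
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return status
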