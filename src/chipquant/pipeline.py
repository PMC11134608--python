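"""End-to-end orchestration: filter -> merge replicates -> normalize ->
pileup/noise -> score -> call -> pool/merge -> count -> test.

Stages communicate through on-disk standard formats (BED/BEDPE, BedGraph,
narrowPeak, TSV) so each is independently inspectable and testable.  A run
manifest captures every parameter, seed, and per-stage record count needed
to re-execute the run.

Two scale-factor estimations are performed.  Peak-discovery tracks are
normalized with factors estimated jointly on the down-sample-merged
per-condition samples (those are the samples actually compared against
each other during discovery); the differential count matrix instead
carries factors estimated on the per-replicate ChIP samples, which a
replicated test requires.  Each pulldown group (ChIP vs Input) is
normalized separately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .intervals_io import (
    FragmentSet,
    GenomeLayout,
    RegionSet,
    downsample_merge,
    filter_fragments,
    read_fragments,
    write_fragments,
)
from .normalization import ScaleFactors, estimate_scale_factors
from .peak_calling import (
    PeakCallParams,
    call_peaks,
    merge_condition_peaks,
    poisson_pvalue_track,
    qvalue_track,
)
from .pileup import (
    NoiseParams,
    build_noise_track,
    median_fragment_length,
    normalize_track,
    paired_pileup,
)
from .differential import count_in_peaks, nb_wald_test

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    samples: pd.DataFrame  # sample_id, role, condition, replicate, path
    layout: GenomeLayout
    outdir: Path
    seed: int = 0
    exclusion: RegionSet | None = None
    max_fragment_length: int = 1000
    dedupe: bool = True
    bin_width: int = 75
    change_threshold: float = 0.33
    min_pooled_density: float = 0.0
    ext_small: int = 500
    ext_large: int = 5000
    noise_floor: float = 2.0
    q_cutoff: float = 0.01
    max_gap: int = 75
    min_length: int | None = None  # None -> the Input's median fragment length
    count_mode: str = "overlap"

    def __post_init__(self):
        required = {"sample_id", "role", "condition", "replicate", "path"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        bad = ~self.samples["role"].isin(["ChIP", "Input"])
        if bad.any():
            raise ValueError("role must be ChIP or Input for every sample")
        for cond, grp in self.samples.groupby("condition"):
            roles = set(grp["role"])
            if "ChIP" in roles and "Input" not in roles:
                raise ValueError(f"condition {cond!r} has ChIP but no matched Input")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML config; relative paths resolve against the YAML."""
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        base = path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        sheet = pd.read_csv(_resolve(cfg["sample_sheet"]), sep="\t")
        sheet["path"] = [str(_resolve(p)) for p in sheet["path"]]
        layout = GenomeLayout.from_chrom_sizes(
            _resolve(cfg["chrom_sizes"]),
            cfg.get("effective_genome_size"),
        )
        exclusion = None
        if cfg.get("exclusion_bed"):
            exclusion = RegionSet.from_bed(_resolve(cfg["exclusion_bed"]))
        params = cfg.get("parameters", {}) or {}
        return cls(
            samples=sheet,
            layout=layout,
            outdir=_resolve(cfg.get("outdir", "chipquant_out")),
            seed=int(cfg.get("seed", 0)),
            exclusion=exclusion,
            **params,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "chipquant",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: getattr(config, k)
            for k in (
                "seed", "max_fragment_length", "dedupe", "bin_width",
                "change_threshold", "min_pooled_density", "ext_small",
                "ext_large", "noise_floor", "q_cutoff", "max_gap",
                "min_length", "count_mode",
            )
        },
        "samples": config.samples.to_dict(orient="records"),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, **info):
        manifest["stages"].setdefault(stage, {}).update(info)

    def emit(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    # stage 1: read + filter every sample
    (out / "filtered").mkdir(exist_ok=True)
    filtered: dict[str, FragmentSet] = {}
    for row in config.samples.itertuples(index=False):
        fs = read_fragments(
            row.path, config.layout,
            sample_id=row.sample_id, role=row.role, condition=str(row.condition),
        )
        fs, stats = filter_fragments(
            fs, config.exclusion, config.max_fragment_length, config.dedupe
        )
        filtered[row.sample_id] = fs
        p = out / "filtered" / f"{row.sample_id}.bed"
        write_fragments(fs, p)
        emit(p)
        record("filter", **{row.sample_id: asdict(stats)})

    conditions = sorted(
        set(config.samples.loc[config.samples["role"] == "ChIP", "condition"].astype(str))
    )

    def reps(cond: str, role: str) -> list[FragmentSet]:
        sel = config.samples[
            (config.samples["condition"].astype(str) == cond)
            & (config.samples["role"] == role)
        ]
        return [filtered[s] for s in sel["sample_id"]]

    # stage 2: replicate down-sample-and-merge per condition and role
    merged_chip: dict[str, FragmentSet] = {}
    merged_input: dict[str, FragmentSet] = {}
    for i, cond in enumerate(conditions):
        merged_chip[cond] = downsample_merge(reps(cond, "ChIP"), seed=config.seed + 2 * i)
        merged_input[cond] = downsample_merge(reps(cond, "Input"), seed=config.seed + 2 * i + 1)
        record("merge_replicates", **{
            cond: {
                "chip_fragments": merged_chip[cond].n_fragments,
                "input_fragments": merged_input[cond].n_fragments,
            }
        })

    # stage 3: scale factors
    def factors_or_unity(sets: list[FragmentSet]) -> ScaleFactors:
        if len(sets) >= 2:
            return estimate_scale_factors(
                sets, config.layout, config.bin_width,
                config.change_threshold, config.min_pooled_density,
            )
        return ScaleFactors({sets[0].sample_id: 1.0})

    chip_merged_factors = factors_or_unity([merged_chip[c] for c in conditions])
    input_merged_factors = factors_or_unity([merged_input[c] for c in conditions])
    chip_reps = [filtered[s] for s in config.samples.loc[
        config.samples["role"] == "ChIP", "sample_id"
    ]]
    replicate_factors = factors_or_unity(chip_reps)
    p = out / "scale_factors.tsv"
    replicate_factors.to_tsv(p)
    emit(p)
    record(
        "normalize",
        merged_chip_factors=chip_merged_factors.factors,
        merged_input_factors=input_merged_factors.factors,
        replicate_chip_factors=replicate_factors.factors,
        n_bins_used=replicate_factors.n_bins_used,
    )

    # stages 4-6: per-condition tracks, scoring, peak calling
    peaksets = {}
    for cond in conditions:
        chip_fs, input_fs = merged_chip[cond], merged_input[cond]
        d = median_fragment_length(input_fs)
        noise, lambda_bg = build_noise_track(
            input_fs,
            NoiseParams(
                d=d,
                effective_genome_size=config.layout.effective_genome_size,
                ext_small=config.ext_small,
                ext_large=config.ext_large,
                floor=config.noise_floor,
            ),
            input_scale_factor=input_merged_factors[input_fs.sample_id],
        )
        chip_track = normalize_track(
            paired_pileup(chip_fs), chip_merged_factors[chip_fs.sample_id]
        )
        score = qvalue_track(poisson_pvalue_track(chip_track, noise))
        params = PeakCallParams(
            q_cutoff=config.q_cutoff,
            min_length=config.min_length if config.min_length else d,
            max_gap=config.max_gap,
        )
        peaks = call_peaks(score, params, chip=chip_track)
        peaksets[cond] = peaks
        for name, track in (
            ("chip", chip_track), ("noise", noise), ("score", score.neglog10q)
        ):
            p = out / f"{cond}_{name}.bedgraph"
            track.to_bedgraph(p)
            emit(p)
        p = out / f"{cond}_peaks.narrowPeak"
        peaks.to_narrowpeak(p, name_prefix=f"{cond}_peak")
        emit(p)
        record("call_peaks", **{
            cond: {
                "d": d, "lambda_bg": lambda_bg, "n_peaks": len(peaks),
                "min_length": params.min_length, "max_gap": params.max_gap,
                "q_cutoff": params.q_cutoff,
            }
        })

    # stage 7: consensus peaks across conditions
    consensus = merge_condition_peaks(peaksets)
    p = out / "consensus_peaks.bed"
    consensus.to_bed(p)
    emit(p)
    record("merge_peaks", n_consensus=len(consensus))

    # stage 8: per-replicate counting in consensus peaks
    cm = count_in_peaks(consensus, chip_reps, mode=config.count_mode)
    cm.factors = dict(replicate_factors.factors)
    p = out / "counts.tsv"
    cm.to_tsv(p)
    emit(p)
    record("count", n_peaks=len(cm.peaks), samples=cm.samples)

    # stage 9: differential binding (two conditions, >=2 reps each)
    design = {
        str(r.sample_id): str(r.condition)
        for r in config.samples.itertuples(index=False)
        if r.role == "ChIP"
    }
    rep_counts = pd.Series(design).value_counts()
    if len(conditions) == 2 and (rep_counts >= 2).all() and len(cm.peaks) > 0:
        db = nb_wald_test(cm, design)
        p = out / "differential_binding.tsv"
        db.to_csv(p, sep="\t", index=False, float_format="%.8g")
        emit(p)
        record(
            "test",
            n_tested=len(db),
            n_significant=int((db["padj"] <= 0.05).sum()),
        )
    else:
        record("test", skipped="needs 2 conditions with >= 2 ChIP replicates and >= 1 peak")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
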