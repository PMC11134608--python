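"""Synthetic paired-end ChIP/Input experiments with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a shared Poisson background of fragments along the genome, enriched peak
regions where ChIP samples receive extra fragments in proportion to a
per-condition fold occupancy, per-sample sequencing-depth multipliers,
a truncated-normal fragment-length distribution, injected positional
duplicates, and artifact-prone exclusion regions.  Fragment midpoints are
the placed primitive so pileups are symmetric around peak centers.

It does not model sequence content, mappability or GC bias, or the
irregular background autocorrelation of real chromatin — conclusions from
synthetic benchmarks are about the algorithms under the stated model, not
about any particular real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intervals_io import FragmentSet, GenomeLayout, RegionSet, write_bedpe

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "simulate_null_pair",
    "simulate_to_dir",
    "simulate_count_matrix",
    "match_peaks",
]


@dataclass
class SimConfig:
    """Study conditions of a simulated two-condition ChIP experiment.

    Defaults describe a compact but realistic design: one 2 Mb chromosome,
    background 0.02 fragments/bp (~4x mean coverage at 200 bp fragments),
    two conditions with two ChIP + two Input replicates each, 50 peaks of
    ~500 bp at 8-fold occupancy, 5% duplicate fragments, and a handful of
    2 kb exclusion regions kept clear of peaks.
    """

    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: {"chrSim": 2_000_000})
    background_density: float = 0.02  # fragments per bp per unit depth
    n_peaks: int = 50
    peak_width: int = 500
    peak_width_jitter: int = 100
    enrichment_fold: float = 8.0
    db_fraction: float = 0.0
    db_fold: float = 4.0  # fold multiplier applied to the second condition
    conditions: tuple[str, ...] = ("A", "B")
    n_replicates: int = 2
    depth_multipliers: dict[str, float] | None = None
    frag_length_mean: float = 200.0
    frag_length_sd: float = 20.0
    frag_length_min: int = 50
    duplicate_rate: float = 0.05
    n_exclusion: int = 4
    exclusion_width: int = 2000

    def __post_init__(self):
        if self.background_density <= 0:
            raise ValueError("background_density must be positive")
        if self.enrichment_fold < 1 or self.db_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        if self.depth_multipliers is not None:
            if any(m <= 0 for m in self.depth_multipliers.values()):
                raise ValueError("depth multipliers must be positive")
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chromosomes)

    def sample_names(self) -> list[str]:
        out = []
        for cond in self.conditions:
            for role in ("ChIP", "Input"):
                for rep in range(1, self.n_replicates + 1):
                    out.append(f"{cond}_{role}_rep{rep}")
        return out

    def multiplier(self, sample: str) -> float:
        if self.depth_multipliers is None:
            return 1.0
        return self.depth_multipliers.get(sample, 1.0)


@dataclass
class SimTruth:
    """Ground truth emitted next to the simulated fragments."""

    peaks: pd.DataFrame  # chrom, start, end, is_db + fold_<condition> columns
    depth_multipliers: dict[str, float]
    realized_counts: dict[str, int]
    exclusion: RegionSet
    config: SimConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peaks": self.peaks.to_dict(orient="list"),
            "peaks_columns": list(self.peaks.columns),
            "depth_multipliers": self.depth_multipliers,
            "realized_counts": self.realized_counts,
            "exclusion": [list(iv) for iv in self.exclusion.intervals()],
            "config": _config_dict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["chromosomes"] = {k: int(v) for k, v in cfg["chromosomes"].items()}
        cfg["conditions"] = tuple(cfg["conditions"])
        return cls(
            peaks=pd.DataFrame(payload["peaks"])[payload["peaks_columns"]],
            depth_multipliers=payload["depth_multipliers"],
            realized_counts=payload["realized_counts"],
            exclusion=RegionSet.from_intervals(
                [(c, int(s), int(e)) for c, s, e in payload["exclusion"]]
            ),
            config=SimConfig(**cfg),
        )


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["conditions"] = list(cfg.conditions)
    return d


def _sample_rng(seed: int, cond_idx: int, role: str, rep: int) -> np.random.Generator:
    # fixed per-sample offsets so adding samples never perturbs existing ones
    offset = cond_idx * 1000 + (0 if role == "ChIP" else 500) + rep
    return np.random.default_rng([seed, offset])


def _place_peaks(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping peaks at least 2x the mean width apart."""
    rows = []
    chroms = list(cfg.chromosomes.items())
    total = sum(L for _, L in chroms)
    remaining = cfg.n_peaks
    for ci, (chrom, L) in enumerate(chroms):
        k = remaining if ci == len(chroms) - 1 else round(cfg.n_peaks * L / total)
        k = min(k, remaining)
        if k == 0:
            continue
        margin = cfg.peak_width * 2 + cfg.peak_width_jitter
        slot = (L - 2 * margin) / k
        if slot < 2 * cfg.peak_width:
            raise ValueError("cannot place peaks non-overlapping and separated")
        for i in range(k):
            w = int(cfg.peak_width + rng.integers(-cfg.peak_width_jitter, cfg.peak_width_jitter + 1))
            w = max(w, 50)
            lo = margin + i * slot
            center = int(lo + rng.uniform(0.25, 0.75) * slot)
            rows.append((chrom, center - w // 2, center - w // 2 + w))
        remaining -= k
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    n = len(df)
    is_db = np.zeros(n, dtype=bool)
    n_db = int(round(cfg.db_fraction * n))
    if n_db:
        is_db[rng.choice(n, size=n_db, replace=False)] = True
    df["is_db"] = is_db
    for ci, cond in enumerate(cfg.conditions):
        fold = np.full(n, cfg.enrichment_fold)
        if ci >= 1:
            fold[is_db] = cfg.enrichment_fold * cfg.db_fold
        df[f"fold_{cond}"] = fold
    return df


def _place_exclusion(cfg: SimConfig, peaks: pd.DataFrame, rng: np.random.Generator) -> RegionSet:
    """Exclusion regions that avoid overlapping any true peak."""
    ivs = []
    for chrom, L in cfg.chromosomes.items():
        pk = peaks[peaks["chrom"] == chrom]
        placed = 0
        attempts = 0
        while placed < cfg.n_exclusion and attempts < 1000:
            attempts += 1
            s = int(rng.integers(0, max(1, L - cfg.exclusion_width)))
            e = s + cfg.exclusion_width
            if ((pk["start"] < e) & (pk["end"] > s)).any():
                continue
            if any(c == chrom and s < pe and e > ps for c, ps, pe in ivs):
                continue
            ivs.append((chrom, s, e))
            placed += 1
    return RegionSet.from_intervals(ivs)


def _draw_fragments(
    rng: np.random.Generator,
    cfg: SimConfig,
    chrom: str,
    L: int,
    n_background: int,
    peak_rows: pd.DataFrame | None,
    fold_col: str | None,
    mult: float,
) -> np.ndarray:
    mids = [rng.uniform(0, L, size=n_background)]
    if peak_rows is not None and len(peak_rows):
        for r in peak_rows.itertuples(index=False):
            extra_rate = cfg.background_density * (getattr(r, fold_col) - 1.0) * mult
            n_extra = rng.poisson(extra_rate * (r.end - r.start))
            if n_extra:
                mids.append(rng.uniform(r.start, r.end, size=n_extra))
    mid = np.concatenate(mids)
    a = (cfg.frag_length_min - cfg.frag_length_mean) / cfg.frag_length_sd
    lens = stats.truncnorm.rvs(
        a, np.inf, loc=cfg.frag_length_mean, scale=cfg.frag_length_sd,
        size=len(mid), random_state=rng,
    )
    lens = np.maximum(np.round(lens), cfg.frag_length_min).astype(np.int64)
    lens = np.minimum(lens, L)
    start = np.round(mid).astype(np.int64) - lens // 2
    # shift boundary fragments inward so lengths stay distribution-true
    start = np.clip(start, 0, L - lens)
    end = start + lens
    frags = np.stack([start, end], axis=1)
    if cfg.duplicate_rate > 0 and len(frags):
        n_dup = rng.binomial(len(frags), cfg.duplicate_rate)
        if n_dup:
            pick = rng.choice(len(frags), size=n_dup, replace=False)
            frags = np.concatenate([frags, frags[pick]])
    return frags


def simulate_experiment(cfg: SimConfig) -> tuple[dict[str, FragmentSet], SimTruth]:
    """Draw all samples of a two-condition ChIP/Input experiment.

    Background fragment midpoints follow a Poisson process with rate
    ``background_density * depth_multiplier``; ChIP samples additionally
    receive peak fragments at rate ``background_density * (fold - 1) *
    depth_multiplier`` with midpoints uniform in the peak interval.
    """
    layout = cfg.layout()
    master = np.random.default_rng([cfg.seed, 0])
    peaks = _place_peaks(cfg, master)
    exclusion = _place_exclusion(cfg, peaks, master)
    fragsets: dict[str, FragmentSet] = {}
    realized: dict[str, int] = {}
    multipliers: dict[str, float] = {}
    for ci, cond in enumerate(cfg.conditions):
        for role in ("ChIP", "Input"):
            for rep in range(1, cfg.n_replicates + 1):
                name = f"{cond}_{role}_rep{rep}"
                mult = cfg.multiplier(name)
                multipliers[name] = mult
                rng = _sample_rng(cfg.seed, ci, role, rep)
                data = {}
                for chrom, L in cfg.chromosomes.items():
                    n_bg = rng.poisson(cfg.background_density * mult * L)
                    pk = peaks[peaks["chrom"] == chrom] if role == "ChIP" else None
                    arr = _draw_fragments(
                        rng, cfg, chrom, L, n_bg, pk,
                        f"fold_{cond}" if role == "ChIP" else None, mult,
                    )
                    if len(arr):
                        data[chrom] = arr
                fs = FragmentSet(name, role, cond, layout, data)
                fragsets[name] = fs
                realized[name] = fs.n_fragments
    truth = SimTruth(peaks, multipliers, realized, exclusion, cfg)
    return fragsets, truth


def simulate_null_pair(cfg: SimConfig) -> tuple[FragmentSet, FragmentSet]:
    """Two samples from the identical peak-free background process
    (possibly at different depths): a ChIP-like sample and an Input."""
    null_cfg = SimConfig(**{**_config_dict(cfg), "n_peaks": 0,
                            "chromosomes": dict(cfg.chromosomes),
                            "conditions": (cfg.conditions[0],),
                            "n_replicates": 1})
    layout = null_cfg.layout()
    out = []
    for role, rep in (("ChIP", 1), ("Input", 1)):
        name = f"{null_cfg.conditions[0]}_{role}_rep{rep}"
        mult = null_cfg.multiplier(name)
        rng = _sample_rng(null_cfg.seed, 0, role, rep)
        data = {}
        for chrom, L in null_cfg.chromosomes.items():
            n_bg = rng.poisson(null_cfg.background_density * mult * L)
            arr = _draw_fragments(rng, null_cfg, chrom, L, n_bg, None, None, mult)
            if len(arr):
                data[chrom] = arr
        out.append(FragmentSet(name, role, null_cfg.conditions[0], layout, data))
    return out[0], out[1]


def simulate_to_dir(cfg: SimConfig, outdir: str | Path) -> tuple[dict[str, FragmentSet], SimTruth]:
    """Run :func:`simulate_experiment` and write BEDPE per sample, the
    chromosome-sizes table, the exclusion BED, and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fragsets, truth = simulate_experiment(cfg)
    layout = cfg.layout()
    layout.to_chrom_sizes(outdir / "chrom.sizes")
    truth.exclusion.to_bed(outdir / "exclusion.bed")
    truth.to_json(outdir / "truth.json")
    truth.peaks.to_csv(outdir / "true_peaks.tsv", sep="\t", index=False)
    for name, fs in fragsets.items():
        write_bedpe(fs, outdir / f"{name}.bedpe")
    return fragsets, truth


def simulate_count_matrix(
    n_peaks: int = 2000,
    n_reps: int = 3,
    dispersion: float = 0.1,
    mean_log: float = 4.5,
    sd_log: float = 0.6,
    fold: float = 1.0,
    db_fraction: float = 0.0,
    seed: int = 0,
):
    """Negative-binomial count matrix for differential-binding calibration.

    Per-peak base means are lognormal; a ``db_fraction`` of peaks get the
    second condition's mean multiplied by ``fold``.  Returns
    ``(counts ndarray (n_peaks, 2*n_reps), sample names, design dict,
    db_labels boolean array)``.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean_log, sd_log, size=n_peaks)
    is_db = np.zeros(n_peaks, dtype=bool)
    n_db = int(round(db_fraction * n_peaks))
    if n_db:
        is_db[rng.choice(n_peaks, size=n_db, replace=False)] = True
    mu_a = base
    mu_b = np.where(is_db, base * fold, base)
    r = 1.0 / dispersion

    def draw(mu, n):
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(len(mu), n))

    counts = np.concatenate([draw(mu_a, n_reps), draw(mu_b, n_reps)], axis=1)
    names = [f"condA_rep{i+1}" for i in range(n_reps)] + [
        f"condB_rep{i+1}" for i in range(n_reps)
    ]
    design = {n: ("condA" if n.startswith("condA") else "condB") for n in names}
    return counts, names, design, is_db


def match_peaks(
    truth: pd.DataFrame,
    called: pd.DataFrame,
    min_reciprocal: float = 0.5,
) -> tuple[float, float, int, int, int]:
    """Reciprocal-overlap matching of called peaks against truth.

    A pair matches when the overlap covers at least ``min_reciprocal`` of
    BOTH intervals.  Returns (sensitivity, precision, tp, fp, fn) where tp
    counts matched truth peaks and fp counts called peaks matching no
    truth peak.
    """
    def _overlaps(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
        hit = np.zeros(len(a), dtype=bool)
        for i, r in enumerate(a.itertuples(index=False)):
            cand = b[(b["chrom"] == r.chrom) & (b["start"] < r.end) & (b["end"] > r.start)]
            for c in cand.itertuples(index=False):
                ov = min(r.end, c.end) - max(r.start, c.start)
                if ov >= min_reciprocal * (r.end - r.start) and ov >= min_reciprocal * (c.end - c.start):
                    hit[i] = True
                    break
        return hit

    truth = truth[["chrom", "start", "end"]]
    called = called[["chrom", "start", "end"]]
    tp = int(_overlaps(truth, called).sum())
    fn = len(truth) - tp
    matched_called = int(_overlaps(called, truth).sum())
    fp = len(called) - matched_called
    sens = tp / len(truth) if len(truth) else 1.0
    prec = matched_called / len(called) if len(called) else 1.0
    return sens, prec, tp, fp, fn
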