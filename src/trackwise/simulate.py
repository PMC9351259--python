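"""Synthetic multi-omics track generator with planted statistical structure.

Emulates the shape of real multi-condition interval datasets (expression
tracks, peak-score tracks, methylation-level tracks, value-less peak tracks)
on a toy genome: non-overlapping genes placed uniformly per chromosome, one
or more intervals per gene per track, and per-gene values drawn from a
Gaussian copula so that associations of known strength can be planted
between any pair of columns regardless of their scales (the latent normal is
transformed to a log-normal, normal or thresholded-categorical margin).

Everything is driven by a single seed; the returned truth record stores all
planted parameters for downstream recovery checks.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from scipy.stats import norm

from .core import AttachedColumn, GeneAnnotation, GenomicInterval, Scale, ScaleKind, Track
from .track_io import Config, TrackSpec, scale_to_spec, write_config

__all__ = [
    "PlantedEffect",
    "SyntheticSpec",
    "TrackDef",
    "default_spec",
    "generate_dataset",
    "null_spec",
    "planted_pair_spec",
    "write_fixture",
]


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", text.lower()).strip("_")


@dataclass
class TrackDef:
    """One synthetic track: margin family plus interval geometry.

    ``scale`` is a JSON-style spec ("rational", "interval",
    {"ordinal": [...]}, {"binary": [...]}, {"nominal": [...]}) or None for a
    value-less track that only contributes interval counts.  ``missing_rate``
    is the probability that a gene receives no interval at all, which becomes
    a not-defined cell after aggregation.
    """

    technology: str
    condition: str
    scale: Any = "rational"
    column_name: str = "value"
    id: str = ""
    intervals_per_gene: float = 1.0  # mean count for covered genes (>= 1)
    missing_rate: float = 0.0
    lognorm_mu: float = 2.0
    lognorm_sigma: float = 0.25
    normal_mu: float = 0.0
    normal_sd: float = 1.0
    level_probs: list[float] | None = None

    def __post_init__(self) -> None:
        if self.intervals_per_gene < 1:
            raise ValueError("intervals_per_gene must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def has_values(self) -> bool:
        return self.scale is not None

    def concrete_scale(self) -> Scale | None:
        if self.scale is None:
            return None
        if isinstance(self.scale, Scale):
            return self.scale
        if isinstance(self.scale, str):
            return Scale(ScaleKind(self.scale))
        (kind, levels), = self.scale.items()
        return Scale(ScaleKind(kind), tuple(levels))


@dataclass
class PlantedEffect:
    """Association of known strength between two tracks' value columns.

    ``strength`` is the correlation of the latent Gaussians; the association
    type labels how it surfaces after the margins are applied (a numeric
    correlation, a categorical dependence, or a location shift of a numeric
    column across categories).
    """

    track_a: str
    track_b: str
    kind: str = "pearson_rho"  # pearson_rho | categorical_dependence | cat_num_shift
    strength: float = 0.8

    def __post_init__(self) -> None:
        if not (-1 <= self.strength <= 1):
            raise ValueError(f"planted strength must satisfy |rho| <= 1, got {self.strength}")
        if self.kind not in ("pearson_rho", "categorical_dependence", "cat_num_shift"):
            raise ValueError(f"unknown association type {self.kind!r}")


@dataclass
class SyntheticSpec:
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (1_000, 5_000)
    tracks: list[TrackDef] = field(default_factory=list)
    planted: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0


def default_spec(n_genes: int = 500, seed: int = 0,
                 conditions: Sequence[str] = ("wildtype", "knockout", "rescue")) -> SyntheticSpec:
    """Three base technologies across three conditions, nine value tracks.

    Mirrors the structure of a typical multi-condition epigenomics study:
    per condition one RNA-seq expression track (log-normal, rational), one
    ChIP-seq peak-score track (log-normal, rational, sparse coverage) and one
    methylation-level track (three ordered categories, bimodal-ish margins).
    Replicate-like correlations are planted between the expression tracks of
    neighbouring conditions.
    """
    tracks: list[TrackDef] = []
    for cond in conditions:
        tracks.append(
            TrackDef(
                technology="RNA-seq", condition=cond, scale="rational",
                column_name="expression", intervals_per_gene=1.0, missing_rate=0.05,
                lognorm_mu=3.0, lognorm_sigma=0.8,
            )
        )
        tracks.append(
            TrackDef(
                technology="ChIP H3K4me3", condition=cond, scale="rational",
                column_name="score", intervals_per_gene=1.4, missing_rate=0.35,
                lognorm_mu=2.0, lognorm_sigma=0.5,
            )
        )
        tracks.append(
            TrackDef(
                technology="RRBS", condition=cond,
                scale={"ordinal": ["low", "medium", "high"]},
                column_name="methylation", intervals_per_gene=2.0, missing_rate=0.1,
                level_probs=[0.45, 0.1, 0.45],  # bimodal methylation levels
            )
        )
    spec = SyntheticSpec(n_genes=n_genes, seed=seed, tracks=tracks)
    ids = [_track_id(i, t) for i, t in enumerate(tracks)]
    rna = [tid for tid, t in zip(ids, tracks) if t.technology == "RNA-seq"]
    spec.planted = [
        PlantedEffect(rna[0], rna[1], "pearson_rho", 0.7),
        PlantedEffect(rna[1], rna[2], "pearson_rho", 0.7),
    ]
    return spec


def null_spec(n_columns: int = 20, n_genes: int = 500, seed: int = 0) -> SyntheticSpec:
    """Mutually independent columns across the scale families (no planted effects)."""
    tracks = []
    cycle = [
        ("rational", "expression"),
        ("interval", "logfc"),
        ({"ordinal": ["low", "medium", "high"]}, "methylation"),
        ({"binary": ["no", "yes"]}, "mutated"),
    ]
    for i in range(n_columns):
        scale, colname = cycle[i % len(cycle)]
        tracks.append(
            TrackDef(
                technology=f"tech{i % 4}", condition=f"cond{i // 4}",
                scale=scale, column_name=colname, intervals_per_gene=1.0,
                missing_rate=0.02,
            )
        )
    return SyntheticSpec(n_genes=n_genes, seed=seed, tracks=tracks)


def planted_pair_spec(rho: float = 0.8, n_genes: int = 1000, seed: int = 0,
                      sigma: float = 0.25) -> SyntheticSpec:
    """Two rational expression tracks with a planted correlation of ``rho``.

    A small log-scale sigma keeps the log-normal margin nearly linear in the
    latent Gaussian, so the Pearson correlation of the values stays close to
    the planted latent correlation.
    """
    tracks = [
        TrackDef(technology="RNA-seq", condition="a", scale="rational",
                 column_name="expression", lognorm_sigma=sigma),
        TrackDef(technology="RNA-seq", condition="b", scale="rational",
                 column_name="expression", lognorm_sigma=sigma),
    ]
    spec = SyntheticSpec(n_genes=n_genes, seed=seed, tracks=tracks)
    ids = [_track_id(i, t) for i, t in enumerate(tracks)]
    spec.planted = [PlantedEffect(ids[0], ids[1], "pearson_rho", rho)]
    return spec


def _track_id(index: int, tdef: TrackDef) -> str:
    return tdef.id or f"t{index:02d}_{_slug(tdef.technology)}_{_slug(tdef.condition)}"


def _place_genes(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[str, GenomicInterval]]:
    lo, hi = spec.gene_length_range
    per_chrom = [spec.n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_genes % spec.n_chromosomes):
        per_chrom[i] += 1
    entries: list[tuple[str, GenomicInterval]] = []
    g = 0
    for ci in range(spec.n_chromosomes):
        k = per_chrom[ci]
        if k == 0:
            continue
        chrom = f"chr{ci + 1}"
        lengths = rng.integers(lo, hi + 1, size=k)
        free = spec.chrom_length - int(lengths.sum()) - k  # reserve >= 1 bp gaps
        if free <= 0:
            raise ValueError(
                f"infeasible packing: {k} genes of up to {hi} bp do not fit on "
                f"a {spec.chrom_length} bp chromosome"
            )
        offsets = np.sort(rng.integers(0, free, size=k))
        cum = np.concatenate([[0], np.cumsum(lengths[:-1])])
        starts = offsets + cum + np.arange(k)  # strictly separated
        for j in range(k):
            entries.append(
                (f"gene_{g:05d}", GenomicInterval(chrom, int(starts[j]), int(starts[j] + lengths[j])))
            )
            g += 1
    return entries


def _latent_matrix(spec: SyntheticSpec, ids: list[str], rng: np.random.Generator) -> np.ndarray:
    n_cols = len(ids)
    corr = np.eye(n_cols)
    pos = {tid: i for i, tid in enumerate(ids)}
    for eff in spec.planted:
        for tid in (eff.track_a, eff.track_b):
            if tid not in pos:
                raise ValueError(f"planted effect names unknown track {tid!r}")
        i, j = pos[eff.track_a], pos[eff.track_b]
        corr[i, j] = corr[j, i] = eff.strength
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("planted correlation structure is not positive definite") from None
    z = rng.standard_normal((spec.n_genes, n_cols))
    return z @ chol.T


def _margin(tdef: TrackDef, z: np.ndarray) -> list:
    scale = tdef.concrete_scale()
    assert scale is not None
    if scale.kind is ScaleKind.RATIONAL:
        return [float(v) for v in np.exp(tdef.lognorm_mu + tdef.lognorm_sigma * z)]
    if scale.kind is ScaleKind.INTERVAL:
        return [float(v) for v in tdef.normal_mu + tdef.normal_sd * z]
    levels = scale.levels
    assert levels is not None
    probs = tdef.level_probs or [1 / len(levels)] * len(levels)
    if len(probs) != len(levels) or abs(sum(probs) - 1) > 1e-9:
        raise ValueError(f"level_probs must be a distribution over {len(levels)} levels")
    cuts = norm.ppf(np.cumsum(probs[:-1]))
    idx = np.searchsorted(cuts, z)
    return [levels[int(i)] for i in idx]


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[Track], GeneAnnotation, dict]:
    """Generate tracks, annotation and the truth record, fully seed-deterministic.

    Per gene each track draws its interval count (zero with probability
    ``missing_rate``, otherwise 1 + Poisson(mean - 1)) and places the
    intervals inside the gene body, so the nearest-feature assignment is
    unambiguous.  All intervals of a gene carry the gene's value, hence any
    within-gene aggregator reproduces it exactly.
    """
    if not spec.tracks:
        raise ValueError("spec declares no tracks")
    rng = np.random.default_rng(spec.seed)
    entries = _place_genes(spec, rng)
    annotation = GeneAnnotation(entries=entries, source="gene-model")
    n_genes = len(entries)

    ids = [_track_id(i, t) for i, t in enumerate(spec.tracks)]
    if len(set(ids)) != len(ids):
        raise ValueError("track ids are not unique")
    value_ids = [tid for tid, t in zip(ids, spec.tracks) if t.has_values]
    latent = _latent_matrix(spec, value_ids, rng) if value_ids else np.empty((n_genes, 0))
    latent_col = {tid: k for k, tid in enumerate(value_ids)}

    tracks: list[Track] = []
    for tid, tdef in zip(ids, spec.tracks):
        gene_values = _margin(tdef, latent[:, latent_col[tid]]) if tdef.has_values else None
        covered = rng.random(n_genes) >= tdef.missing_rate
        extra = rng.poisson(max(tdef.intervals_per_gene - 1.0, 0.0), size=n_genes)
        intervals: list[GenomicInterval] = []
        values: list = []
        for g, (fid, giv) in enumerate(entries):
            if not covered[g]:
                continue
            count = 1 + int(extra[g])
            for _ in range(count):
                max_len = min(1000, giv.length)
                ilen = int(rng.integers(max(max_len // 2, 1), max_len + 1))
                istart = int(rng.integers(giv.start, giv.end - ilen + 1))
                intervals.append(GenomicInterval(giv.chrom, istart, istart + ilen))
                if gene_values is not None:
                    values.append(gene_values[g])
        columns = (
            [AttachedColumn(tdef.column_name, values, tdef.concrete_scale())]
            if tdef.has_values
            else []
        )
        tracks.append(
            Track(id=tid, technology=tdef.technology, condition=tdef.condition,
                  intervals=intervals, columns=columns)
        )

    truth = {
        "seed": spec.seed,
        "n_genes": n_genes,
        "columns": {
            tid: (f"{tid}.{t.column_name}" if t.has_values else f"{tid}.count")
            for tid, t in zip(ids, spec.tracks)
        },
        "planted": [
            {
                "col_a": f"{eff.track_a}.{spec.tracks[ids.index(eff.track_a)].column_name}",
                "col_b": f"{eff.track_b}.{spec.tracks[ids.index(eff.track_b)].column_name}",
                "kind": eff.kind,
                "strength": eff.strength,
            }
            for eff in spec.planted
        ],
    }
    return tracks, annotation, truth


def write_fixture(
    tracks: Sequence[Track],
    annotation: GeneAnnotation,
    outdir: str | Path,
    truth: dict | None = None,
    seed: int = 0,
) -> Path:
    """Write a generated dataset as plain-text files plus a runnable config.

    Value tracks become TSV tables, value-less tracks BED3, the annotation a
    named BED; the emitted ``config.json`` loads cleanly and drives the full
    pipeline.  Returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs: list[TrackSpec] = []
    for track in tracks:
        if track.columns:
            path = outdir / f"{track.id}.tsv"
            names = [c.name for c in track.columns]
            with path.open("w") as fh:
                fh.write("\t".join(["chrom", "start", "end"] + names) + "\n")
                for i, iv in enumerate(track.intervals):
                    row = [iv.chrom, str(iv.start), str(iv.end)]
                    for c in track.columns:
                        v = c.values[i]
                        if isinstance(v, float):
                            row.append(f"{v:.12g}")
                        else:
                            row.append("NA" if v is None else str(v))
                    fh.write("\t".join(row) + "\n")
            specs.append(
                TrackSpec(
                    path=str(path), format="tsv", technology=track.technology,
                    condition=track.condition, id=track.id,
                    scales={
                        c.name: scale_to_spec(c.scale)
                        for c in track.columns
                        if isinstance(c.scale, Scale)
                    },
                )
            )
        else:
            path = outdir / f"{track.id}.bed"
            with path.open("w") as fh:
                for iv in track.intervals:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            specs.append(
                TrackSpec(path=str(path), format="bed", technology=track.technology,
                          condition=track.condition, id=track.id)
            )

    ann_path = outdir / "annotation.bed"
    with ann_path.open("w") as fh:
        for fid, iv in annotation.entries:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fid}\t0\t{iv.strand}\n")

    config = Config(tracks=specs, annotation=str(ann_path), annotation_format="bed", seed=seed)
    config_path = outdir / "config.json"
    write_config(config, config_path)
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return config_path
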