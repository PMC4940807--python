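"""Synthetic two-state expression data with known ground truth.

The generator emulates the shape of a curated two-condition microarray
study: a probes x samples matrix, per-sample annotations (disease state,
smoking status, gender), a noisy background and a handful of planted
large-effect genes shifted in the "cancer" groups.  It exists so every
pipeline stage is testable end-to-end without downloads: the planted ids are
the known answer a frontier analysis should recover.

The background is symmetric unimodal (normal) by default; a heavy-tailed
log-normal option exercises the mean/median divergence that makes the two
performance measures genuinely conflicting.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .frontier import CriteriaTable


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults mirror a modest two-group microarray comparison: 500 probes,
    control/cancer groups of 15 and 16 samples (never-smoker arm sizes of the
    lung study this package targets), 5 planted genes shifted by 10 noise
    standard deviations.

    Parameters
    ----------
    n_genes : total probe count
    group_sizes : map group label -> sample count
    n_planted : number of large-effect genes (always the first rows)
    effect_size : shift added to planted genes in the shifted groups,
        in expression units
    noise_sd : background standard deviation (expression units)
    baseline : background location
    seed : RNG seed; generation is fully reproducible
    shifted_groups : group labels receiving the planted shift
        (the "cancer" side)
    distribution : "normal" or "lognormal" background noise
    """

    n_genes: int = 500
    group_sizes: Dict[str, int] = dataclasses.field(
        default_factory=lambda: {"control": 15, "cancer": 16})
    n_planted: int = 5
    effect_size: float = 10.0
    noise_sd: float = 1.0
    baseline: float = 8.0
    seed: int = 0
    shifted_groups: Tuple[str, ...] = ("cancer",)
    distribution: str = "normal"

    def __post_init__(self):
        if self.n_genes < 1 or self.n_planted < 0:
            raise ValueError("counts must be positive")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        unknown = set(self.shifted_groups) - set(self.group_sizes)
        if unknown:
            raise ValueError(f"shifted_groups not in group_sizes: {unknown}")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


def generate_dataset(spec: SyntheticSpec) -> Tuple[ExpressionDataset, list]:
    """Generate a dataset and the list of planted probe ids.

    Background values are i.i.d. around ``baseline`` with sd ``noise_sd`` in
    every group; the first ``n_planted`` probes receive a shift of magnitude
    ``effect_size`` in the ``shifted_groups`` samples.  Annotations mimic a
    curated GEO dataset (disease state / stress / gender subsets).

    When several genes are planted, their effects are spread along a
    mean-versus-median tradeoff: gene 0 gets the largest median shift
    (``1.5 x effect_size``, applied uniformly) and the smallest mean shift
    (``0.5 x``), the last planted gene the reverse, with the average of the
    two shifts always ``effect_size``.  The unequal split is realized by
    giving a sub-median minority of the shifted samples an extra offset,
    which moves the group mean without moving its median.  This makes the
    planted set mutually nondominated by construction — the situation the
    frontier method is built for — so for effects well clear of the noise
    the first frontier of a mean+median analysis is exactly the planted set.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = sum(spec.group_sizes.values())
    if spec.distribution == "normal":
        values = rng.normal(spec.baseline, spec.noise_sd,
                            size=(spec.n_genes, n_samples))
    else:
        # log-normal with median `baseline` and scale chosen so the
        # log-space sd matches noise_sd/baseline (heavy right tail)
        sigma = spec.noise_sd / max(abs(spec.baseline), 1e-9)
        values = spec.baseline * rng.lognormal(0.0, sigma,
                                               size=(spec.n_genes, n_samples))

    sample_ids, groups = [], []
    for label, count in spec.group_sizes.items():
        for i in range(count):
            sample_ids.append(f"S{label}{i + 1:02d}")
            groups.append(label)
    k = spec.n_planted
    for p in range(k):
        t = 0.5 if k == 1 else p / (k - 1)
        median_shift = spec.effect_size * (1.5 - t)
        mean_shift = spec.effect_size * (0.5 + t)
        for label in spec.shifted_groups:
            cols = np.flatnonzero(np.asarray(groups, dtype=object) == label)
            values[p, cols] += median_shift
            # extra offset on a minority (< half) of samples: shifts the
            # group mean to mean_shift while leaving the median untouched
            minority = max(1, len(cols) // 3)
            values[p, cols[-minority:]] += ((mean_shift - median_shift)
                                            * len(cols) / minority)

    ann = pd.DataFrame(index=pd.Index(sample_ids))
    ann["disease state"] = ["lung cancer" if g in spec.shifted_groups else "control"
                            for g in groups]
    ann["group"] = groups
    smoking = {"never": "never smoked", "current": "currently smoking"}
    ann["stress"] = [next((v for k, v in smoking.items() if k in g.lower()),
                          "never smoked") for g in groups]
    ann["gender"] = ["female" if i % 2 else "male" for i in range(n_samples)]

    probe_ids = [f"PROBE{i + 1:05d}" for i in range(spec.n_genes)]
    symbols = [f"GENE{i + 1}" for i in range(spec.n_genes)]
    dataset = ExpressionDataset(probe_ids, symbols, sample_ids, values, ann)
    return dataset, probe_ids[:spec.n_planted]


def worked_example() -> CriteriaTable:
    """The canonical six-gene, two-criteria example (minimization sense).

    Its Pareto-efficient frontier is {g1, g5, g6} at the default penalty
    W = 1000 (membership cutoff 2000).
    """
    values = np.array([[1, 4], [3, 4], [5, 6], [7, 5], [3, 2], [4, 1]],
                      dtype=np.float64)
    return CriteriaTable([f"g{i}" for i in range(1, 7)], values, ["m1", "m2"])


def write_soft_fixture(path, n_genes: int = 6, seed: int = 42) -> Tuple[list, list]:
    """Write a miniature GDS-dialect SOFT file (n_genes probes x 8 samples,
    two subset types) for exercising the reader; synthetic stand-in for a
    downloaded GEO dataset.  Returns (probe_ids, sample_ids)."""
    spec = SyntheticSpec(n_genes=n_genes,
                         group_sizes={"control": 4, "cancer": 4},
                         n_planted=1, effect_size=5.0, seed=seed)
    dataset, _ = generate_dataset(spec)
    ann = dataset.sample_annotations
    lines = [
        "^DATABASE = Geo",
        "!Database_name = synthetic fixture",
        "^DATASET = SYN0001",
        "!dataset_title = synthetic two-state fixture",
        f"!dataset_sample_count = {dataset.n_samples}",
    ]
    for key in ("disease state", "stress"):
        for value in pd.unique(ann[key]):
            members = [s for s in dataset.sample_ids if ann.loc[s, key] == value]
            lines += [
                f"^SUBSET = SYN0001_{key[:3]}_{value[:4]}".replace(" ", ""),
                "!subset_dataset_id = SYN0001",
                f"!subset_description = {value}",
                f"!subset_sample_id = {','.join(members)}",
                f"!subset_type = {key}",
            ]
    lines += ["^DATASET = SYN0001", "!dataset_table_begin"]
    lines.append("\t".join(["ID_REF", "IDENTIFIER"] + dataset.sample_ids))
    for i, pid in enumerate(dataset.probe_ids):
        row = [pid, dataset.gene_symbols[i]]
        for j in range(dataset.n_samples):
            v = dataset.values[i, j]
            row.append("null" if np.isnan(v) else f"{v:.4f}")
        lines.append("\t".join(row))
    lines += ["!dataset_table_end"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return dataset.probe_ids, dataset.sample_ids
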