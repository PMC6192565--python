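"""Synthetic fixtures: planted-hierarchy score tables and toy structure sets.

The generators fabricate everything the pipeline consumes — a 4-level
hierarchical ground truth, long-format pairwise score tables with planted
class structure, per-method Gaussian noise and heterogeneous coverage,
and minimal single-chain PDB files whose C-alpha geometry mirrors the
label hierarchy — so every stage is testable without any download.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .score_model import ClassificationLabel, DomainRecord, ScoreTable, write_ground_truth
from .psc_engine import PSCMethodSpec, write_method_config


@dataclass
class PlantedConfig:
    """Planted 4-level hierarchy with per-method noise and coverage.

    ``level_separations[k]`` is the dissimilarity added when two labels
    diverge at level k+1 (a pair differing already in class accumulates
    all four).  ``method_noise`` maps method name to the SD of Gaussian
    noise added to the true dissimilarity; ``method_coverage`` to the
    fraction of unordered pairs the method scores.  Defaults plant a
    64-domain dataset (4 classes x 2 x 2 x 2 x 2) with three methods of
    graded noise and one with partial coverage, emulating the
    heterogeneous-coverage regime of real multi-method experiments.
    """

    n_classes: int = 4
    folds_per_class: int = 2
    superfams_per_fold: int = 2
    families_per_superfam: int = 2
    domains_per_family: int = 2
    level_separations: tuple[float, float, float, float] = (1.0, 0.5, 0.25, 0.125)
    method_noise: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.02, "beta": 0.05, "gamma": 0.10}
    )
    method_coverage: dict[str, float] = field(
        default_factory=lambda: {"alpha": 1.0, "beta": 1.0, "gamma": 0.8}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_classes,
            self.folds_per_class,
            self.superfams_per_fold,
            self.families_per_superfam,
            self.domains_per_family,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all hierarchy counts must be >= 1")
        if any(s < 0 for s in self.level_separations):
            raise ValueError("level separations must be >= 0")
        for m, cov in self.method_coverage.items():
            if not 0 < cov <= 1:
                raise ValueError(f"coverage for {m!r} must be in (0, 1]")
        for m in self.method_noise:
            self.method_coverage.setdefault(m, 1.0)

    @property
    def n_domains(self) -> int:
        return (
            self.n_classes
            * self.folds_per_class
            * self.superfams_per_fold
            * self.families_per_superfam
            * self.domains_per_family
        )

    @property
    def methods(self) -> list[str]:
        return sorted(self.method_noise)


def generate_labels(config: PlantedConfig) -> list[DomainRecord]:
    """Deterministic enumeration of the hierarchy with synthetic IDs d0001..."""
    records = []
    counter = itertools.count(1)
    classes = "abcdefghijklmnopqrstuvwxyz"
    for c in range(config.n_classes):
        for f in range(config.folds_per_class):
            for s in range(config.superfams_per_fold):
                for fam in range(config.families_per_superfam):
                    for _ in range(config.domains_per_family):
                        i = next(counter)
                        label = ClassificationLabel(
                            (classes[c % 26], str(f + 1), str(s + 1), str(fam + 1))
                        )
                        records.append(DomainRecord(f"d{i:04d}", label))
    return records


def true_dissimilarity(
    label_a: ClassificationLabel,
    label_b: ClassificationLabel,
    separations: Sequence[float],
) -> float:
    """Sum of the separations of every level at which the labels diverge."""
    total = 0.0
    for k in range(4):
        if label_a.levels[: k + 1] != label_b.levels[: k + 1]:
            total += separations[k]
    return total


def generate_planted_scores(
    records: Sequence[DomainRecord], config: PlantedConfig
) -> ScoreTable:
    """Multi-method raw dissimilarity table with planted structure.

    Per unordered pair: true dissimilarity from the label hierarchy, plus
    method-specific Gaussian noise; records then thinned independently per
    method to its coverage fraction.  All draws come from the config seed.
    """
    rng = np.random.default_rng(config.seed)
    ids = [r.domain_id for r in records]
    labels = {r.domain_id: r.label for r in records}
    pairs = list(itertools.combinations(sorted(ids), 2))
    base = np.array(
        [true_dissimilarity(labels[a], labels[b], config.level_separations) for a, b in pairs]
    )
    rows = []
    for method in config.methods:
        sigma = config.method_noise[method]
        if np.isinf(sigma):
            # signal-free method: pure noise, no planted structure
            noisy = rng.normal(0.0, 1.0, size=len(pairs))
        else:
            noisy = base + rng.normal(0.0, sigma, size=len(pairs))
        keep = rng.random(len(pairs)) < config.method_coverage[method]
        for (a, b), x, k in zip(pairs, noisy, keep):
            if k:
                rows.append({"domain1": a, "domain2": b, "method": method, "raw": float(x)})
    df = pd.DataFrame(rows, columns=["domain1", "domain2", "method", "raw"])
    return ScoreTable(df, config.methods, sorted(ids))


def planted_method_specs(config: PlantedConfig) -> list[PSCMethodSpec]:
    """Dissimilarity-polarity specs matching the planted score table."""
    return [
        PSCMethodSpec(m, polarity="dissimilarity", runner="builtin:usm")
        for m in config.methods
    ]


def _helix_trace(length: int, rise: float, turn_deg: float, radius: float) -> np.ndarray:
    """Ideal helical C-alpha trace (alpha-helix defaults: 1.5 A rise, ~100 deg)."""
    t = np.arange(length)
    theta = np.deg2rad(turn_deg) * t
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * t]
    )


def _strand_trace(length: int, spacing: float = 3.4) -> np.ndarray:
    """Extended-strand trace with a slight pleat."""
    t = np.arange(length)
    return np.column_stack([spacing * t, 0.9 * (-1.0) ** t, np.zeros(length)])


def generate_toy_structures(
    records: Sequence[DomainRecord],
    outdir: str | Path,
    config: PlantedConfig,
) -> Path:
    """Write one minimal PDB file per domain plus the ground-truth file.

    Per family a base backbone is generated — alternate classes use
    helical vs extended geometry, folds set the length regime, superfamily
    and family perturb the base shape — and the domains of a family are
    the base plus small seeded coordinate jitter, so structural similarity
    decays with label divergence.  Returns the ground-truth file path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)

    base_cache: dict[tuple[str, ...], np.ndarray] = {}
    class_ids = sorted({r.label.levels[0] for r in records})
    fold_lengths = {}
    for rec in records:
        cls, fold = rec.label.levels[0], rec.label.levels[1]
        key = (cls, fold)
        if key not in fold_lengths:
            # length regime per fold, deterministic in the key (crc, not hash():
            # the latter is salted per process)
            fold_lengths[key] = 30 + 10 * (zlib.crc32(".".join(key).encode()) % 6)
    for rec in records:
        fam_key = rec.label.levels
        if fam_key not in base_cache:
            cls, fold = fam_key[0], fam_key[1]
            length = int(np.clip(fold_lengths[(cls, fold)], 30, 80))
            helical = class_ids.index(cls) % 2 == 0
            if helical:
                turn = 100.0 + 4.0 * int(fam_key[2])
                base = _helix_trace(length, rise=1.5, turn_deg=turn, radius=2.3)
            else:
                base = _strand_trace(length, spacing=3.2 + 0.1 * int(fam_key[2]))
            # family-level deterministic bend
            bend = 0.05 * int(fam_key[3]) * np.sin(np.linspace(0, np.pi, length))
            base = base + np.column_stack([bend, np.zeros(length), np.zeros(length)])
            base_cache[fam_key] = base
        base = base_cache[fam_key]
        coords = base + rng.normal(0.0, 0.15, size=base.shape)
        pdb_path = outdir / f"{rec.domain_id}.pdb"
        _write_ca_pdb(coords, pdb_path)
        rec.structure_path = pdb_path

    gt_path = outdir / "ground_truth.txt"
    write_ground_truth(records, gt_path)
    return gt_path


def _write_ca_pdb(coords: np.ndarray, path: Path) -> None:
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA A{i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_planted_dataset(
    config: PlantedConfig, outdir: str | Path
) -> dict[str, Path]:
    """Materialize a complete planted dataset on disk.

    Writes ground truth, structures, the long-format score CSV and a
    matching method-spec config; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_labels(config)
    gt = generate_toy_structures(records, outdir / "structures", config)
    table = generate_planted_scores(records, config)
    scores_csv = outdir / "scores.csv"
    table.df.to_csv(scores_csv, index=False)
    methods_cfg = outdir / "methods.cfg"
    write_method_config(planted_method_specs(config), methods_cfg)
    return {
        "ground_truth": gt,
        "structures": outdir / "structures",
        "scores": scores_csv,
        "methods": methods_cfg,
    }
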