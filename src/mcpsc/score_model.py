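"""Core data types and file I/O for pairwise structure-comparison scores.

The exchange object between all pipeline stages is the :class:`ScoreTable`,
a long-format table of pairwise records (domain1, domain2, method, raw
score, dissimilarity, scaled similarity, imputed flag).  Ground truth is a
plain-text file mapping each domain ID to a dotted 4-level hierarchical
classification label (class.fold.superfamily.family, e.g. ``a.1.1.1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["domain1", "domain2", "method", "raw", "dissimilarity", "scaled", "imputed"]

CONSENSUS_COLUMNS = ["m1", "m2", "m3", "m4", "m5", "median"]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ClassificationLabel:
    """4-level hierarchical label: (class, fold, superfamily, family)."""

    levels: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ValueError(f"label must have exactly 4 components, got {self.levels!r}")
        if any(not part for part in self.levels):
            raise ValueError(f"label has an empty component: {self.levels!r}")

    @classmethod
    def from_string(cls, text: str) -> "ClassificationLabel":
        parts = tuple(text.strip().split("."))
        if len(parts) != 4:
            raise ValueError(f"label {text!r} does not have 4 dot-separated components")
        return cls(parts)  # type: ignore[arg-type]

    def matches(self, other: "ClassificationLabel", level: int) -> bool:
        """True iff the first *level* components are equal (1 <= level <= 4)."""
        if not 1 <= level <= 4:
            raise ValueError(f"level must be in 1..4, got {level}")
        return self.levels[:level] == other.levels[:level]

    def __str__(self) -> str:
        return ".".join(self.levels)


@dataclass
class DomainRecord:
    """A protein domain: unique ID, classification label, optional structure file."""

    domain_id: str
    label: ClassificationLabel
    structure_path: Path | None = None


@dataclass
class ScalingParams:
    """Per-method autoscaling statistics: mean and population SD of dissimilarities."""

    method: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class ScoreTable:
    """Long-format collection of pairwise scores for one or more methods.

    ``df`` has columns ``domain1, domain2, method, raw`` and, once the
    consensus pipeline has run on it, ``dissimilarity, scaled, imputed``.
    Self-pairs are excluded; the full ordered-pair universe for N domains
    has P = N^2 - N rows per method.
    """

    df: pd.DataFrame
    methods: list[str] = field(default_factory=list)
    domains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("domain1", "domain2", "method", "raw"):
            if col not in self.df.columns:
                raise ValueError(f"score table missing column {col!r}")
        if (self.df["domain1"] == self.df["domain2"]).any():
            bad = self.df.loc[self.df["domain1"] == self.df["domain2"], "domain1"].iloc[0]
            raise ValueError(f"self-pair not allowed (domain {bad!r})")
        if self.df.duplicated(subset=["domain1", "domain2", "method"]).any():
            raise ValueError("duplicate (domain1, domain2, method) records")
        if not self.methods:
            self.methods = sorted(self.df["method"].unique())
        if not self.domains:
            self.domains = sorted(set(self.df["domain1"]) | set(self.df["domain2"]))

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_ordered_pairs(self) -> int:
        """P = N^2 - N, the size of the full ordered-pair universe."""
        n = self.n_domains
        return n * n - n

    def coverage(self) -> dict[str, float]:
        """Per-method fraction of the P ordered pairs with a non-missing raw score."""
        counts = self.df.dropna(subset=["raw"]).groupby("method").size()
        p = self.n_ordered_pairs
        return {m: float(counts.get(m, 0)) / p for m in self.methods}

    def copy(self) -> "ScoreTable":
        return ScoreTable(self.df.copy(), list(self.methods), list(self.domains))


def read_ground_truth(path: str | Path) -> list[DomainRecord]:
    """Parse a whitespace-delimited ground-truth file.

    Each non-comment line: ``domain_id  class.fold.superfamily.family
    [structure_filename]``.  ``#`` starts a comment line.  Relative
    structure filenames are resolved against the file's directory.
    """
    path = Path(path)
    records: list[DomainRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'domain_id label [file]', got {line!r}")
        domain_id, label_text = fields[0], fields[1]
        if domain_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate domain_id {domain_id!r}")
        seen.add(domain_id)
        try:
            label = ClassificationLabel.from_string(label_text)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        structure_path = None
        if len(fields) >= 3:
            structure_path = Path(fields[2])
            if not structure_path.is_absolute():
                structure_path = path.parent / structure_path
        records.append(DomainRecord(domain_id, label, structure_path))
    return records


def write_ground_truth(records: Iterable[DomainRecord], path: str | Path) -> None:
    path = Path(path)
    lines = []
    for rec in records:
        parts = [rec.domain_id, str(rec.label)]
        if rec.structure_path is not None:
            parts.append(Path(rec.structure_path).name)
        lines.append(" ".join(parts))
    path.write_text("\n".join(lines) + "\n")


def read_pdb_ca(path: str | Path) -> tuple[np.ndarray, str]:
    """Extract the C-alpha trace of the first model / first chain of a PDB file.

    Returns an (L, 3) float array of coordinates in Angstrom and the
    matching one-letter residue sequence ('X' for non-standard residues).
    Only the first altLoc encountered per residue is kept; unparseable
    ATOM lines are skipped with a logged warning.
    """
    path = Path(path)
    coords: list[tuple[float, float, float]] = []
    seq: list[str] = []
    chain: str | None = None
    seen_res: set[str] = set()
    for line in path.read_text().splitlines():
        if line.startswith("ENDMDL"):
            break  # first model only
        if not line.startswith("ATOM"):
            continue
        if line[12:16].strip() != "CA":
            continue
        try:
            this_chain = line[21]
            res_key = line[22:27]  # resSeq + iCode
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            resname = line[17:20].strip()
        except (ValueError, IndexError):
            logger.warning("skipping unparseable ATOM line in %s: %r", path, line)
            continue
        if chain is None:
            chain = this_chain
        if this_chain != chain:
            continue
        if res_key in seen_res:
            continue  # later altLoc of an already-seen residue
        seen_res.add(res_key)
        coords.append((x, y, z))
        seq.append(_THREE_TO_ONE.get(resname, "X"))
    if not coords:
        raise ValueError(f"empty structure: no CA atoms found in {path}")
    return np.asarray(coords, dtype=float), "".join(seq)


def read_scores_csv(path: str | Path) -> ScoreTable:
    """Read a long-format pairwise score table (domain1, domain2, method, raw)."""
    df = pd.read_csv(path, dtype={"domain1": str, "domain2": str, "method": str})
    missing = {"domain1", "domain2", "method", "raw"} - set(df.columns)
    if missing:
        raise ValueError(f"score csv {path} missing columns {sorted(missing)}")
    return ScoreTable(df[["domain1", "domain2", "method", "raw"]].copy())


def write_scores_csv(table: ScoreTable, path: str | Path) -> None:
    cols = [c for c in LONG_COLUMNS if c in table.df.columns]
    table.df.sort_values(["method", "domain1", "domain2"]).to_csv(path, index=False, columns=cols)


def mirror_symmetric(table: ScoreTable) -> ScoreTable:
    """Add the mirrored record (b, a) for every (a, b) lacking a counterpart.

    Existing counterparts are never overwritten; if both orientations are
    present with different raw scores (external methods may be asymmetric),
    both are kept and a warning logged.  Idempotent.
    """
    df = table.df
    keys = set(zip(df["domain1"], df["domain2"], df["method"]))
    swapped = df.copy()
    swapped[["domain1", "domain2"]] = df[["domain2", "domain1"]].to_numpy()
    need = [
        (d2, d1, m) not in keys
        for d1, d2, m in zip(df["domain1"], df["domain2"], df["method"])
    ]
    mirrored = swapped.loc[need]

    # report asymmetric duplicates (both orientations present, raw differs)
    have_both = df.loc[[not n for n in need]]
    if len(have_both):
        merged = have_both.merge(
            df, left_on=["domain2", "domain1", "method"],
            right_on=["domain1", "domain2", "method"], suffixes=("", "_rev"),
        )
        conflict = merged.loc[
            ~np.isclose(merged["raw"].astype(float), merged["raw_rev"].astype(float), equal_nan=True)
        ]
        for row in conflict.itertuples(index=False):
            logger.warning(
                "asymmetric scores for pair (%s, %s) method %s: %s vs %s",
                row.domain1, row.domain2, row.method, row.raw, row.raw_rev,
            )
    out = pd.concat([df, mirrored], ignore_index=True)
    return ScoreTable(out, list(table.methods), list(table.domains))


def write_consensus_csv(wide: pd.DataFrame, methods: Sequence[str], path: str | Path) -> None:
    """Write the consensus output table (one row per ordered domain pair).

    Columns: domain1, domain2, one scaled-score column per method,
    m1..m5, median, and one ``<method>_imputed`` flag per method.
    Rows sorted by (domain1, domain2).
    """
    cols = ["domain1", "domain2"] + list(methods) + CONSENSUS_COLUMNS + [
        f"{m}_imputed" for m in methods
    ]
    missing = set(cols) - set(wide.columns)
    if missing:
        raise ValueError(f"consensus table missing columns {sorted(missing)}")
    wide.sort_values(["domain1", "domain2"])[cols].to_csv(path, index=False)


def read_consensus_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"domain1": str, "domain2": str})
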