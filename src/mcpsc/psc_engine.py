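"""Pluggable pairwise structure-comparison scoring.

Two self-contained built-in scorers are provided so the consensus stage
works without any third-party binaries:

* ``usm`` — a compression-based (normalized-compression-distance style)
  dissimilarity between C-alpha contact maps.  Representation-agnostic.
* ``kabsch`` — a similarity derived from the RMSD of the optimal rigid
  superposition of the two C-alpha traces (truncated to common length).

External method binaries are wrapped via a command template with
``{pdb1}``/``{pdb2}`` placeholders and a stdout-extraction regex; a
failing, missing or hung binary degrades coverage instead of aborting
the run.  All P x M fine-grained jobs are distributed over p worker
threads; the result table is deterministic for any p because results
are keyed by (pair, method), never by completion order.
"""

from __future__ import annotations

import bz2
import itertools
import logging
import re
import shlex
import subprocess
import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .score_model import DomainRecord, ScoreTable, read_pdb_ca

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 8.0  # Angstrom, C-alpha
KABSCH_R0 = 3.0  # Angstrom, RMSD softening scale for the similarity transform

_COMPRESSORS: dict[str, Callable[[bytes], bytes]] = {
    "zlib": lambda b: zlib.compress(b, 9),
    "bz2": lambda b: bz2.compress(b, 9),
}


@dataclass
class PSCMethodSpec:
    """Declaration of one scorer.

    ``runner`` is ``"builtin:usm"``, ``"builtin:kabsch"`` or
    ``"external:<command template>"`` where the template contains the
    ``{pdb1}`` and ``{pdb2}`` placeholders.  ``polarity`` states whether
    the raw score grows with similarity or with dissimilarity.
    ``expert_weight`` is the prior used by the expert-weighted consensus
    scheme (convention: 1.0 for structure-aware methods, 0.5 for
    structure-agnostic compression-based ones).
    """

    name: str
    polarity: str = "dissimilarity"  # or "similarity"
    runner: str = "builtin:usm"
    pattern: str | None = None  # stdout-extraction regex for external runners
    expert_weight: float = 1.0
    timeout: float = 120.0

    def __post_init__(self) -> None:
        if self.polarity not in ("similarity", "dissimilarity"):
            raise ValueError(f"polarity must be similarity|dissimilarity, got {self.polarity!r}")
        if self.expert_weight <= 0:
            raise ValueError("expert_weight must be > 0")
        if self.runner.startswith("external:"):
            tmpl = self.runner[len("external:"):]
            if "{pdb1}" not in tmpl or "{pdb2}" not in tmpl:
                raise ValueError("external command template needs {pdb1} and {pdb2} placeholders")
            if not self.pattern:
                raise ValueError("external runner requires a stdout-extraction pattern")


def builtin_specs() -> list[PSCMethodSpec]:
    """The two bundled scorers with their conventional polarities and priors."""
    return [
        PSCMethodSpec("usm", polarity="dissimilarity", runner="builtin:usm", expert_weight=0.5),
        PSCMethodSpec("kabsch", polarity="similarity", runner="builtin:kabsch", expert_weight=1.0),
    ]


@dataclass
class JobBatch:
    """All-to-all (or listed) pairs x methods, to be run on ``threads`` workers."""

    pairs: list[tuple[str, str]]
    methods: list[PSCMethodSpec]
    threads: int = 1

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    @property
    def n_jobs(self) -> int:
        return len(self.pairs) * len(self.methods)


def enumerate_pairs(
    domains: Sequence[DomainRecord],
    mode: str = "all_to_all",
    pair_list: Iterable[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """The N(N-1)/2 unordered pairs as lexicographically ordered tuples.

    ``pair_list`` mode filters nothing but validates that every named
    domain is known.
    """
    if len(domains) < 2:
        raise ValueError("need at least 2 domains")
    ids = [d.domain_id for d in domains]
    if mode == "all_to_all":
        return list(itertools.combinations(sorted(ids), 2))
    if mode == "pair_list":
        if pair_list is None:
            raise ValueError("pair_list mode requires a pair list")
        known = set(ids)
        pairs = list(pair_list)
        offenders = sorted({d for p in pairs for d in p if d not in known})
        if offenders:
            raise ValueError(f"pair list names unknown domains: {offenders}")
        return pairs
    raise ValueError(f"unknown mode {mode!r}")


def contact_map(coords: np.ndarray, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """Binary C-alpha contact map: 1 iff distance <= cutoff and |i-j| >= 2."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 coordinates")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    d = squareform(pdist(coords))
    n = len(coords)
    idx = np.arange(n)
    near_diag = np.abs(idx[:, None] - idx[None, :]) < 2
    return ((d <= cutoff) & ~near_diag).astype(np.uint8)


def _serialize_map(cmap: np.ndarray) -> bytes:
    # canonical row-major byte string, one char per cell
    return np.where(cmap > 0, b"1"[0], b"0"[0]).astype(np.uint8).tobytes()


def usm_distance(map_a: np.ndarray, map_b: np.ndarray, compressor: str = "zlib") -> float:
    """Compression-based dissimilarity between two contact maps.

    ``max(C(ab) - C(a), C(ba) - C(b)) / max(C(a), C(b))`` with C(x) the
    compressed byte length; clamped to >= 0.  Symmetric by construction.
    """
    try:
        compress = _COMPRESSORS[compressor]
    except KeyError:
        raise ValueError(f"unknown compressor {compressor!r}") from None
    a = _serialize_map(np.asarray(map_a))
    b = _serialize_map(np.asarray(map_b))
    ca = len(compress(a))
    cb = len(compress(b))
    cab = len(compress(a + b))
    cba = len(compress(b + a))
    return max(0.0, max(cab - ca, cba - cb) / max(ca, cb))


def kabsch_similarity(coords_a: np.ndarray, coords_b: np.ndarray, r0: float = KABSCH_R0) -> float:
    """Similarity in (0, 1] from optimal-superposition RMSD of the CA traces.

    Both traces are truncated to the common leading length L, centred, and
    superposed by the optimal proper rotation (reflections excluded);
    returns 1 / (1 + RMSD / r0).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 residues per structure")
    L = min(len(a), len(b))
    a = a[:L] - a[:L].mean(axis=0)
    b = b[:L] - b[:L].mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    rmsd = rssd / np.sqrt(L)
    return 1.0 / (1.0 + rmsd / r0)


def run_external_method(
    spec: PSCMethodSpec,
    pdb1: str | Path,
    pdb2: str | Path,
    timeout: float | None = None,
) -> float | None:
    """Invoke an external PSC binary on one pair; None on any failure.

    Nonzero exit status, timeout, or no regex match all yield a missing
    score (recorded, not fatal) so a flaky binary only lowers coverage.
    """
    if not spec.runner.startswith("external:"):
        raise ValueError(f"{spec.name} is not an external method")
    template = spec.runner[len("external:"):]
    cmd = template.format(pdb1=str(pdb1), pdb2=str(pdb2))
    try:
        proc = subprocess.run(
            shlex.split(cmd),
            capture_output=True,
            text=True,
            timeout=timeout if timeout is not None else spec.timeout,
        )
    except (subprocess.TimeoutExpired, FileNotFoundError, OSError) as exc:
        logger.warning("%s failed on (%s, %s): %s", spec.name, pdb1, pdb2, exc)
        return None
    if proc.returncode != 0:
        logger.warning("%s exited %d on (%s, %s)", spec.name, proc.returncode, pdb1, pdb2)
        return None
    match = re.search(spec.pattern, proc.stdout)
    if not match:
        logger.warning("%s produced no score on (%s, %s)", spec.name, pdb1, pdb2)
        return None
    try:
        return float(match.group(1) if match.groups() else match.group(0))
    except ValueError:
        logger.warning("%s produced unparseable score %r", spec.name, match.group(0))
        return None


@dataclass
class _StructureCache:
    """Lazily loaded per-domain coordinates and contact maps."""

    records: dict[str, DomainRecord]
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    _coords: dict[str, np.ndarray | None] = field(default_factory=dict)
    _maps: dict[str, np.ndarray | None] = field(default_factory=dict)

    def coords(self, domain_id: str) -> np.ndarray | None:
        if domain_id not in self._coords:
            rec = self.records[domain_id]
            if rec.structure_path is None:
                self._coords[domain_id] = None
            else:
                try:
                    self._coords[domain_id] = read_pdb_ca(rec.structure_path)[0]
                except (OSError, ValueError) as exc:
                    logger.warning("cannot read structure for %s: %s", domain_id, exc)
                    self._coords[domain_id] = None
        return self._coords[domain_id]

    def cmap(self, domain_id: str) -> np.ndarray | None:
        if domain_id not in self._maps:
            c = self.coords(domain_id)
            self._maps[domain_id] = None if c is None else contact_map(c, self.cutoff)
        return self._maps[domain_id]


def _run_one(
    spec: PSCMethodSpec,
    pair: tuple[str, str],
    cache: _StructureCache,
    compressor: str,
) -> float | None:
    d1, d2 = pair
    if spec.runner == "builtin:usm":
        m1, m2 = cache.cmap(d1), cache.cmap(d2)
        if m1 is None or m2 is None:
            return None
        return usm_distance(m1, m2, compressor)
    if spec.runner == "builtin:kabsch":
        c1, c2 = cache.coords(d1), cache.coords(d2)
        if c1 is None or c2 is None:
            return None
        try:
            return kabsch_similarity(c1, c2)
        except ValueError:
            return None
    if spec.runner.startswith("external:"):
        r1 = cache.records[d1].structure_path
        r2 = cache.records[d2].structure_path
        if r1 is None or r2 is None:
            return None
        return run_external_method(spec, r1, r2)
    raise ValueError(f"unknown runner {spec.runner!r} for method {spec.name}")


def distribute_jobs(
    batch: JobBatch,
    records: Sequence[DomainRecord],
    compressor: str = "zlib",
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ScoreTable:
    """Run all pairs x methods jobs over ``batch.threads`` workers.

    The output is keyed by (pair, method) and therefore bit-identical for
    any thread count.  External methods whose binary cannot be resolved at
    all are disabled up front with a warning (coverage 0 for that method);
    individually failed jobs simply leave that record's raw score missing.
    """
    rec_map = {r.domain_id: r for r in records}
    cache = _StructureCache(rec_map, cutoff=contact_cutoff)

    active: list[PSCMethodSpec] = []
    for spec in batch.methods:
        if spec.runner.startswith("external:"):
            exe = shlex.split(spec.runner[len("external:"):])[0]
            from shutil import which

            if which(exe) is None and not Path(exe).exists():
                logger.warning("binary %r for method %s not found; method disabled", exe, spec.name)
                continue
        active.append(spec)

    jobs = [(spec, pair) for spec in batch.methods for pair in batch.pairs]
    results: dict[tuple[str, str, str], float | None] = {}

    def work(job: tuple[PSCMethodSpec, tuple[str, str]]) -> tuple[tuple[str, str, str], float | None]:
        spec, pair = job
        if spec not in active:
            return (pair[0], pair[1], spec.name), None
        return (pair[0], pair[1], spec.name), _run_one(spec, pair, cache, compressor)

    # warm the cache serially so lazy loads are race-free
    for rec in records:
        cache.cmap(rec.domain_id)

    if batch.threads == 1:
        for job in jobs:
            key, val = work(job)
            results[key] = val
    else:
        with ThreadPoolExecutor(max_workers=batch.threads) as pool:
            for key, val in pool.map(work, jobs):
                results[key] = val

    rows = [
        {"domain1": d1, "domain2": d2, "method": m, "raw": results[(d1, d2, m)]}
        for spec in batch.methods
        for (d1, d2) in batch.pairs
        for m in [spec.name]
    ]
    df = pd.DataFrame(rows, columns=["domain1", "domain2", "method", "raw"])
    df["raw"] = df["raw"].astype(float)
    return ScoreTable(df, [s.name for s in batch.methods], sorted(rec_map))


def read_method_config(path: str | Path) -> list[PSCMethodSpec]:
    """Parse a plain-text method-spec config.

    One method per stanza; ``key = value`` lines; stanzas separated by
    ``[name]`` headers.  Recognised keys: polarity, runner, command,
    pattern, expert_weight, timeout.  ``command`` is shorthand for
    ``runner = external:<command>``.
    """
    path = Path(path)
    specs: list[PSCMethodSpec] = []
    current: dict[str, str] | None = None

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        kwargs: dict = {"name": current.pop("name")}
        if "command" in current:
            kwargs["runner"] = "external:" + current.pop("command")
        for key in ("polarity", "runner", "pattern"):
            if key in current:
                kwargs[key] = current.pop(key)
        if "expert_weight" in current:
            kwargs["expert_weight"] = float(current.pop("expert_weight"))
        if "timeout" in current:
            kwargs["timeout"] = float(current.pop("timeout"))
        if current:
            raise ValueError(f"unknown keys in method config: {sorted(current)}")
        specs.append(PSCMethodSpec(**kwargs))
        current = None

    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            current = {"name": line[1:-1].strip()}
            continue
        if current is None:
            raise ValueError(f"method config line outside a [name] stanza: {line!r}")
        key, _, value = line.partition("=")
        current[key.strip()] = value.strip()
    flush()
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate method names in config")
    return specs


def write_method_config(specs: Sequence[PSCMethodSpec], path: str | Path) -> None:
    lines = []
    for spec in specs:
        lines.append(f"[{spec.name}]")
        lines.append(f"polarity = {spec.polarity}")
        lines.append(f"runner = {spec.runner}")
        if spec.pattern:
            lines.append(f"pattern = {spec.pattern}")
        lines.append(f"expert_weight = {spec.expert_weight}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
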