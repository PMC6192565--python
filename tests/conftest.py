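import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mcpsc.score_model import ClassificationLabel, DomainRecord, ScoreTable
from mcpsc.psc_engine import PSCMethodSpec
from mcpsc.synthetic_data import (
    PlantedConfig,
    generate_labels,
    generate_planted_scores,
    generate_toy_structures,
    planted_method_specs,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def random_half_table(
    rng: np.random.Generator,
    n_domains: int,
    n_methods: int,
    keep_prob: float = 0.75,
) -> tuple[ScoreTable, list[PSCMethodSpec]]:
    """Random unordered-pair score table with induced missingness.

    Regenerates (seeded) until every method has at least one score and all
    method pairs share at least one scored pair, so the divergence-weight
    scheme is well defined.
    """
    domains = [f"d{i}" for i in range(n_domains)]
    methods = [f"meth{j}" for j in range(n_methods)]
    pairs = [(a, b) for i, a in enumerate(domains) for b in domains[i + 1:]]
    while True:
        rows = []
        for m in methods:
            for a, b in pairs:
                if rng.random() < keep_prob:
                    rows.append(
                        {"domain1": a, "domain2": b, "method": m, "raw": rng.normal()}
                    )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        got = set(df["method"].unique())
        if got != set(methods):
            continue
        wide = df.pivot(index=["domain1", "domain2"], columns="method", values="raw")
        wide = wide.reindex(columns=methods)
        ok = all(
            (wide[mi].notna() & wide[mj].notna()).any()
            for i, mi in enumerate(methods)
            for mj in methods[i + 1:]
        )
        if ok:
            break
    polarity = {m: ("similarity" if j % 2 else "dissimilarity") for j, m in enumerate(methods)}
    specs = [
        PSCMethodSpec(m, polarity=polarity[m], runner="builtin:usm", expert_weight=1.0 + 0.5 * j)
        for j, m in enumerate(methods)
    ]
    return ScoreTable(df, methods, domains), specs


@pytest.fixture(scope="session")
def planted_zero_noise():
    """64-domain planted hierarchy, zero noise, full coverage, 3 methods."""
    cfg = PlantedConfig(
        method_noise={"alpha": 0.0, "beta": 0.0, "gamma": 0.0},
        method_coverage={"alpha": 1.0, "beta": 1.0, "gamma": 1.0},
        seed=11,
    )
    records = generate_labels(cfg)
    table = generate_planted_scores(records, cfg)
    return cfg, records, table, planted_method_specs(cfg)


@pytest.fixture(scope="session")
def planted_noisy():
    """Planted hierarchy with graded noise and one partial-coverage method."""
    cfg = PlantedConfig(seed=23)
    records = generate_labels(cfg)
    table = generate_planted_scores(records, cfg)
    return cfg, records, table, planted_method_specs(cfg)


@pytest.fixture(scope="session")
def toy_structures(tmp_path_factory):
    """16 toy PDB structures in a 2x2x1x2x2 hierarchy, with ground truth."""
    cfg = PlantedConfig(
        n_classes=2,
        folds_per_class=2,
        superfams_per_fold=1,
        families_per_superfam=2,
        domains_per_family=2,
        seed=5,
    )
    records = generate_labels(cfg)
    outdir = tmp_path_factory.mktemp("structures")
    gt = generate_toy_structures(records, outdir, cfg)
    return cfg, records, gt


def make_label(text: str) -> ClassificationLabel:
    return ClassificationLabel.from_string(text)


def make_records(labels: dict[str, str]) -> list[DomainRecord]:
    return [DomainRecord(d, make_label(s)) for d, s in labels.items()]
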