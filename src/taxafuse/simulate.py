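"""Synthetic fixtures with the statistical pathologies the pipeline targets:
excess zeros, block collinearity and small label-associated effect sizes.

Counts follow a zero-inflated log-normal/Poisson model: per-feature latent
Gaussian variables — correlated within designated blocks — are exponentiated
into Poisson rates spanning several orders of magnitude (the heavy right skew
typical of taxon abundances), then structurally zeroed at the sparsity rate.
Designated signal features receive a per-class latent mean shift. Ground truth
(block membership, signal features) is returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import RANKS, EnrichmentTable, TaxonomyRecord
from .preprocess import AbundanceTable

__all__ = [
    "FixtureSpec",
    "make_abundance",
    "make_enrichment",
    "make_taxonomy",
    "write_taxonomy",
    "write_enrichment",
]


@dataclass
class FixtureSpec:
    """Generator settings; defaults give 200 samples × 60 features, 3 classes,
    three collinear blocks of six features at within-block latent correlation
    0.95, 70% structural zeros (the zero fraction typical of 16S tables), and
    a modest per-class latent shift on the first (signal) block."""

    n_samples: int = 200
    n_features: int = 60
    n_classes: int = 3
    blocks: list[tuple[int, float]] = field(default_factory=lambda: [(6, 0.95), (6, 0.95), (6, 0.95)])
    sparsity: float = 0.7
    effect_sizes: list[float] = field(default_factory=lambda: [-0.6, 0.0, 0.6])
    signal_block: int = 0                 # index into blocks; its features carry the shifts
    latent_scale: float = 2.0             # log-abundance dispersion (orders of magnitude)
    base_log_mean: tuple[float, float] = (np.log(5.0), np.log(50.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sparsity < 1:
            raise ValueError(f"sparsity must lie in [0, 1), got {self.sparsity}")
        if sum(s for s, _ in self.blocks) > self.n_features:
            raise ValueError("block sizes exceed the number of features")
        if len(self.effect_sizes) != self.n_classes:
            raise ValueError("one effect size required per class")
        if not 0 <= self.signal_block < len(self.blocks):
            raise ValueError("signal_block out of range")
        for size, rho in self.blocks:
            if size < 2 or not 0 <= rho < 1:
                raise ValueError(f"invalid block ({size}, {rho})")


def make_abundance(spec: FixtureSpec) -> tuple[AbundanceTable, dict]:
    """Draw an abundance table from the spec; returns (table, ground_truth)
    where ground_truth holds ``blocks`` (feature-index lists), ``signal_features``
    and the latent matrix used."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features

    classes = np.arange(n) % spec.n_classes          # balanced round-robin design
    labels = [f"C{c + 1}" for c in classes]

    latent = rng.standard_normal((n, p))
    block_members: list[list[int]] = []
    start = 0
    for size, rho in spec.blocks:
        idx = list(range(start, start + size))
        z = rng.standard_normal(n)
        latent[:, idx] = np.sqrt(rho) * z[:, None] + np.sqrt(1 - rho) * latent[:, idx]
        block_members.append(idx)
        start += size

    signal = list(block_members[spec.signal_block])
    shifts = np.asarray(spec.effect_sizes)[classes]
    latent[:, signal] += shifts[:, None]

    log_mu = rng.uniform(*spec.base_log_mean, size=p)
    rates = np.exp(log_mu[None, :] + spec.latent_scale * latent)
    counts = rng.poisson(rates).astype(float)
    if spec.sparsity > 0:
        # structural zeros model non-detection of an organism in a sample, so
        # they are shared across a block's features (the same taxon tallied at
        # several ranks) and independent for unblocked features
        mask = rng.random((n, p)) < spec.sparsity
        for idx in block_members:
            shared = rng.random(n) < spec.sparsity
            mask[:, idx] = shared[:, None]
        counts[mask] = 0.0

    table = AbundanceTable(
        values=counts,
        sample_ids=[f"S{i + 1}" for i in range(n)],
        feature_names=[f"Otu{j + 1:05d}" for j in range(p)],
        labels=labels,
    )
    truth = {"blocks": block_members, "signal_features": signal, "latent": latent}
    return table, truth


def make_enrichment(
    microbes: list[str],
    n_studies: int = 20,
    bias_pairs: list[tuple[str, str, float]] | None = None,
    seed: int = 0,
    base_p: float = 0.3,
    diseases: list[str] | None = None,
) -> tuple[EnrichmentTable, np.ndarray, list[str]]:
    """Random study memberships with boosted joint inclusion for bias pairs.

    Returns the table, the exact adjacency counted from the realised study
    sets (occurrences on the diagonal), and the node order of that matrix.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    rng = np.random.default_rng(seed)
    bias_pairs = bias_pairs or []
    diseases = diseases or ["colorectal cancer"]
    records = []
    sets: list[frozenset[str]] = []
    for s in range(n_studies):
        members = {m for m in microbes if rng.random() < base_p}
        for u, v, p_joint in bias_pairs:
            if rng.random() < p_joint:
                members.update((u, v))
        if not members:
            members.add(microbes[int(rng.integers(len(microbes)))])
        fs = frozenset(members)
        sets.append(fs)
        records.append((f"study_{s + 1}", diseases[s % len(diseases)], fs))

    order = sorted(microbes)
    idx = {m: i for i, m in enumerate(order)}
    A = np.zeros((len(order), len(order)), dtype=int)
    for fs in sets:
        present = sorted(fs)
        for i, u in enumerate(present):
            A[idx[u], idx[u]] += 1
            for v in present[i + 1 :]:
                A[idx[u], idx[v]] += 1
                A[idx[v], idx[u]] += 1
    return EnrichmentTable(records=records), A, order


# small pools of plausible clade names for generated lineages
_PHYLA = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria", "Verrucomicrobia"]
_CLASSES = ["Clostridia", "Bacteroidia", "Gammaproteobacteria", "Actinomycetia", "Bacilli"]
_ORDERS = ["Clostridiales", "Bacteroidales", "Enterobacteriales", "Lactobacillales", "Bifidobacteriales"]


def make_taxonomy(
    features: list[str],
    unclassified_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, TaxonomyRecord]:
    """Mothur-style lineages (domain → genus) for OTU-style feature ids; a
    stated fraction receive genus 'unclassified', exercising the ascend-to-
    parent conversion rule. Family and genus names are unique per feature."""
    rng = np.random.default_rng(seed)
    records: dict[str, TaxonomyRecord] = {}
    for i, feat in enumerate(features):
        genus = "unclassified" if rng.random() < unclassified_fraction else f"Genus{i + 1}"
        lineage = [
            ("domain", "Bacteria", 100),
            ("phylum", _PHYLA[i % len(_PHYLA)], 100),
            ("class", _CLASSES[i % len(_CLASSES)], 100),
            ("order", _ORDERS[i % len(_ORDERS)], 100),
            ("family", f"Family{i + 1}", 100),
            ("genus", genus, 100),
        ]
        records[feat] = TaxonomyRecord(otu_id=feat, lineage=lineage)
    return records


def write_taxonomy(records: dict[str, TaxonomyRecord], path: str | Path) -> Path:
    """Serialise taxonomy records in mothur constaxonomy layout
    (OTU / Size / Taxonomy with ``Name(support);`` segments)."""
    path = Path(path)
    rows = []
    for otu, rec in records.items():
        tax = "".join(f"{name}({support});" for _, name, support in rec.lineage)
        rows.append({"OTU": otu, "Size": 1, "Taxonomy": tax})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_enrichment(table: EnrichmentTable, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"study": sid, "disease": disease, "members": ";".join(sorted(members))}
        for sid, disease, members in table.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
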