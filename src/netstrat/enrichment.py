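"""Functional enrichment of proteins, interacting pairs, and modules.

Enrichment is assessed by one-sided (over-representation) Fisher's exact
tests on 2x2 tables of foreground vs background membership against term
carriage, at a default significance cutoff of 5e-4 and with no multiple-
testing correction by default (an optional Benjamini-Hochberg flag emits
q-values alongside).  The universe is restricted to annotated proteins of
the background network; unannotated proteins are excluded from both margins.
Chi-square tests compare annotation-count distributions either across terms
for a pair of networks or across networks for one term.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from netstrat.graph_core import Network

CATEGORIES = ("biological_process", "molecular_function", "cellular_component")

DEFAULT_ALPHA = 5e-4


@dataclass
class AnnotationMap:
    """Protein -> set of (category, term) annotations.

    Terms are opaque, pre-mapped labels (e.g. GO-slim identifiers); a protein
    may carry many terms.
    """

    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    term_labels: dict[str, str] = field(default_factory=dict)

    def add(self, protein: str, category: str, term: str, label: str | None = None) -> None:
        self.annotations.setdefault(protein, set()).add((category, term))
        if label:
            self.term_labels[term] = label

    def proteins(self) -> set[str]:
        return set(self.annotations)

    def terms_of(self, protein: str, category: str | None = None) -> set[str]:
        pairs = self.annotations.get(protein, set())
        return {t for c, t in pairs if category is None or c == category}

    def terms(self, category: str | None = None) -> set[str]:
        out: set[str] = set()
        for pairs in self.annotations.values():
            out |= {t for c, t in pairs if category is None or c == category}
        return out

    def term_counts(self, proteins: set[str], category: str | None = None) -> pd.Series:
        """Number of annotated proteins per term within a protein set."""
        counts: dict[str, int] = defaultdict(int)
        for p in proteins:
            for t in self.terms_of(p, category):
                counts[t] += 1
        return pd.Series(counts, dtype=int).sort_index()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Read a TSV of (protein, category, term_id[, term_label]) rows."""
        amap = cls()
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
                amap.add(cols[0], cols[1], cols[2], cols[3] if len(cols) > 3 else None)
        return amap

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("#protein\tcategory\tterm_id\tterm_label\n")
            for p in sorted(self.annotations):
                for c, t in sorted(self.annotations[p]):
                    fh.write(f"{p}\t{c}\t{t}\t{self.term_labels.get(t, t)}\n")


def _fisher_table(
    fg_counts: pd.Series, fg_total: int, bg_counts: pd.Series, bg_total: int, alpha: float,
    bh: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation p per term.

    The p-value for a term with K background carriers, n foreground members
    and k foreground carriers is P(X >= k) for X ~ Hypergeom(N, K, n),
    identical to the one-sided Fisher exact test of the 2x2 table.
    """
    terms = sorted(bg_counts.index)
    K = bg_counts.reindex(terms).fillna(0).to_numpy(dtype=int)
    k = fg_counts.reindex(terms).fillna(0).to_numpy(dtype=int)
    pvals = stats.hypergeom.sf(k - 1, bg_total, K, fg_total)
    pvals = np.clip(pvals, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "fg_count": k,
            "fg_total": fg_total,
            "bg_count": K,
            "bg_total": bg_total,
            "odds_direction": np.where(
                k / max(fg_total, 1) > K / max(bg_total, 1), "over", "under/equal"
            ),
            "p": pvals,
            "enriched": pvals < alpha,
        },
        index=pd.Index(terms, name="term"),
    )
    if bh:
        order = np.argsort(pvals)
        m = len(pvals)
        q = np.empty(m)
        ranked = pvals[order] * m / (np.arange(m) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        table["q"] = np.clip(q, 0, 1)
    return table


def protein_enrichment(
    foreground: set[str],
    background: set[str],
    annot: AnnotationMap,
    category: str | None = "biological_process",
    alpha: float = DEFAULT_ALPHA,
    bh: bool = False,
) -> pd.DataFrame:
    """Term over-representation of a foreground protein set vs a background.

    Both sets are intersected with the annotated universe; the foreground is
    additionally intersected with the background.
    """
    annotated = {p for p in annot.proteins() if annot.terms_of(p, category)}
    bg = background & annotated
    fg = foreground & bg
    if not fg:
        raise ValueError("foreground has no annotated proteins inside the background")
    return _fisher_table(
        annot.term_counts(fg, category), len(fg), annot.term_counts(bg, category), len(bg),
        alpha, bh,
    )


def _pairs_sharing_terms(
    net: Network, annot: AnnotationMap, category: str | None
) -> tuple[pd.Series, int]:
    """Per-term counts of interacting pairs sharing the term, and the number
    of pairs with both endpoints annotated (the pair universe)."""
    counts: dict[str, int] = defaultdict(int)
    n_pairs = 0
    for a, b in net.sorted_edges():
        ta = annot.terms_of(a, category)
        tb = annot.terms_of(b, category)
        if not ta or not tb:
            continue
        n_pairs += 1
        for t in ta & tb:
            counts[t] += 1
    return pd.Series(counts, dtype=int).sort_index(), n_pairs


def pair_enrichment(
    net: Network,
    background_net: Network,
    annot: AnnotationMap,
    category: str | None = "biological_process",
    alpha: float = DEFAULT_ALPHA,
    bh: bool = False,
) -> pd.DataFrame:
    """Term enrichment counted over interacting pairs sharing the term.

    The unit of counting is an interacting pair whose two partners share the
    term (a pair sharing several terms counts once per shared term); the
    focal network's pairs are tested against the background network's pairs.
    """
    fg_counts, fg_total = _pairs_sharing_terms(net, annot, category)
    bg_counts, bg_total = _pairs_sharing_terms(background_net, annot, category)
    if fg_total == 0 or bg_total == 0:
        raise ValueError("no annotated interacting pairs")
    return _fisher_table(fg_counts, fg_total, bg_counts, bg_total, alpha, bh)


def distribution_chi2(
    counts_a: pd.Series, counts_b: pd.Series, min_expected: float = 1.0
) -> tuple[float, int, float]:
    """Chi-square comparison of two annotation-count vectors.

    ``counts_a`` is treated as observed and ``counts_b`` provides the
    expected proportions (rescaled to the observed total); cells with
    expected count below ``min_expected`` are pooled into an "other" cell.
    Works for among-term vectors of a network pair or among-network vectors
    of one term.  Returns (chi2, df, p).
    """
    idx = counts_a.index.union(counts_b.index)
    obs = counts_a.reindex(idx).fillna(0).to_numpy(dtype=float)
    ref = counts_b.reindex(idx).fillna(0).to_numpy(dtype=float)
    if obs.sum() == 0 or ref.sum() == 0:
        raise ValueError("all-zero count vector")
    exp = ref / ref.sum() * obs.sum()
    small = exp < min_expected
    if small.any():
        keep = ~small
        obs = np.append(obs[keep], obs[small].sum())
        exp = np.append(exp[keep], exp[small].sum())
        if exp[-1] == 0:  # pooled cell still empty in the reference
            obs, exp = obs[:-1], exp[:-1]
    if len(obs) < 2:
        return 0.0, 0, 1.0
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), len(obs) - 1, float(p)


@dataclass
class ModuleEnrichmentSummary:
    """Cross-network summary of per-module enrichment results."""

    enriched_fraction: dict[str, float]
    enriched_terms: dict[str, set[str]]  # network -> terms enriched in >=1 module
    universal_terms: set[str]
    exclusive_terms: dict[str, set[str]]
    conglomerate_only_terms: set[str]
    per_module: pd.DataFrame


def module_enrichment_summary(
    modsets: dict[str, "object"],
    annot: AnnotationMap,
    backgrounds: dict[str, set[str]],
    category: str | None = "biological_process",
    alpha: float = DEFAULT_ALPHA,
    total_name: str | None = None,
    min_module_size: int = 3,
) -> ModuleEnrichmentSummary:
    """Per-module enrichment across networks with universal/exclusive terms.

    For each network, every module of at least ``min_module_size`` proteins
    is tested against that network's protein background.  Universal terms
    are enriched in at least one module of every network; exclusive terms
    are enriched in exactly one network's modules.  Terms exclusive to the
    total (conglomerate-derived) network are flagged as candidate artifacts
    of conglomerate assembly.
    """
    enriched_terms: dict[str, set[str]] = {}
    enriched_fraction: dict[str, float] = {}
    rows: list[dict] = []
    for name in sorted(modsets):
        modset = modsets[name]
        bg = backgrounds[name]
        terms_here: set[str] = set()
        n_mod = 0
        n_enriched = 0
        for i, module in enumerate(modset.modules):
            if len(module) < min_module_size:
                continue
            n_mod += 1
            try:
                table = protein_enrichment(set(module), bg, annot, category, alpha)
            except ValueError:
                continue
            hits = set(table.index[table.enriched])
            if hits:
                n_enriched += 1
                terms_here |= hits
            rows.append(
                {"network": name, "module": i, "size": len(module), "n_enriched_terms": len(hits)}
            )
        enriched_terms[name] = terms_here
        enriched_fraction[name] = n_enriched / n_mod if n_mod else 0.0
    networks = sorted(enriched_terms)
    universal = set.intersection(*(enriched_terms[n] for n in networks)) if networks else set()
    exclusive = {
        n: enriched_terms[n]
        - set.union(set(), *(enriched_terms[m] for m in networks if m != n))
        for n in networks
    }
    conglomerate_only = exclusive.get(total_name, set()) if total_name else set()
    return ModuleEnrichmentSummary(
        enriched_fraction=enriched_fraction,
        enriched_terms=enriched_terms,
        universal_terms=universal,
        exclusive_terms=exclusive,
        conglomerate_only_terms=conglomerate_only,
        per_module=pd.DataFrame(rows),
    )
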