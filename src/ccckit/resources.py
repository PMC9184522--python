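"""Ligand-receptor prior-knowledge resources.

A resource is a set of directed interactions between protein entities: a
transmitter (ligand side) and a receiver (receptor side).  Entities may be
heteromeric complexes of several gene subunits; subunit strings are joined
with ``"_"``.  This module provides the canonical in-memory representation,
complex dissociation, localisation-based filtering, and the descriptive
cross-resource comparisons (uniqueness, pairwise similarity, and category
enrichment against the pooled background of all resources).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinEntity",
    "InteractionRecord",
    "ResourceCollection",
    "AnnotationTable",
    "dissociate_complexes",
    "filter_by_localisation",
    "overlap_stats",
    "pairwise_similarity",
    "category_enrichment",
    "read_resource_csv",
    "write_resource_csv",
    "read_annotation_csv",
]

#: Localisation categories that qualify a receiver as a plasma-membrane
#: protein (transmembrane or peripheral).
PLASMA_MEMBRANE_CATEGORIES = frozenset(
    {"plasma_membrane_transmembrane", "plasma_membrane_peripheral"}
)

#: Enrichment significance tiers, most stringent last.
ENRICHMENT_TIERS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ProteinEntity:
    """One or more gene symbols acting as a single transmitter or receiver.

    Subunits are upper-cased, stripped, de-duplicated and stored sorted, so
    two entities with the same subunits in any order compare equal.  The
    canonical string form joins subunits with ``"_"``.
    """

    subunits: tuple[str, ...]

    def __init__(self, subunits: Iterable[str] | str):
        if isinstance(subunits, str):
            subunits = subunits.split("_")
        cleaned = []
        for s in subunits:
            s = str(s).strip().upper()
            if not s:
                raise ValueError("empty gene symbol in protein entity")
            cleaned.append(s)
        if not cleaned:
            raise ValueError("protein entity needs at least one subunit")
        object.__setattr__(self, "subunits", tuple(sorted(set(cleaned))))

    @classmethod
    def from_string(cls, text: str) -> "ProteinEntity":
        return cls(text)

    @property
    def name(self) -> str:
        """Canonical string form (sorted subunits joined by ``_``)."""
        return "_".join(self.subunits)

    @property
    def is_complex(self) -> bool:
        return len(self.subunits) > 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True, eq=False)
class InteractionRecord:
    """A transmitter → receiver pair with provenance.

    Identity (equality and hashing) is the pair of canonical entities only;
    resource name, categories and curation counts are annotations and do not
    distinguish records.
    """

    transmitter: ProteinEntity
    receiver: ProteinEntity
    resource_name: str = ""
    categories: frozenset[str] = field(default_factory=frozenset)
    curation_refs: int | None = None

    def __post_init__(self):
        if self.curation_refs is not None and self.curation_refs < 0:
            raise ValueError("curation_refs must be a non-negative count")
        object.__setattr__(self, "categories", frozenset(self.categories))

    @property
    def identity(self) -> tuple[str, str]:
        return (self.transmitter.name, self.receiver.name)

    def __eq__(self, other):
        if not isinstance(other, InteractionRecord):
            return NotImplemented
        return self.identity == other.identity

    def __hash__(self):
        return hash(self.identity)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"InteractionRecord({self.transmitter.name} -> {self.receiver.name})"


@dataclass
class ResourceCollection:
    """Named resources, each a set of interaction records."""

    resources: dict[str, set[InteractionRecord]]

    def __post_init__(self):
        for name, records in self.resources.items():
            records = set(records)
            self.resources[name] = records

    def __len__(self):
        return len(self.resources)

    def names(self) -> list[str]:
        return list(self.resources)

    def union(self) -> set[InteractionRecord]:
        out: set[InteractionRecord] = set()
        for records in self.resources.values():
            out |= records
        return out


@dataclass
class AnnotationTable:
    """Gene → category labels, optionally with a localisation consensus score.

    ``percentile`` holds a per-gene consensus percentile in [0, 100]; genes
    without a score are treated as scoring 0 when a threshold is applied.
    """

    categories: dict[str, frozenset[str]]
    percentile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.categories = {
            str(g).strip().upper(): frozenset(str(c) for c in cats if str(c))
            for g, cats in self.categories.items()
        }
        for g, cats in self.categories.items():
            if not cats or any(not c for c in cats):
                raise ValueError(f"gene {g!r} has an empty category label")
        self.percentile = {str(g).strip().upper(): float(p) for g, p in self.percentile.items()}
        for g, p in self.percentile.items():
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"percentile for {g!r} outside [0, 100]: {p}")

    def categories_of(self, gene: str) -> frozenset[str]:
        return self.categories.get(gene.strip().upper(), frozenset())

    def percentile_of(self, gene: str) -> float:
        return self.percentile.get(gene.strip().upper(), 0.0)


# ---------------------------------------------------------------------------
# Complex handling and filtering
# ---------------------------------------------------------------------------

def dissociate_complexes(resource: Iterable[InteractionRecord]) -> set[InteractionRecord]:
    """Expand complex records into all subunit-pair combinations.

    Every output record has a single-subunit transmitter and receiver; the
    result is de-duplicated by identity.  Idempotent: applying it twice gives
    the same set.
    """
    out: set[InteractionRecord] = set()
    for rec in resource:
        for t, r in itertools.product(rec.transmitter.subunits, rec.receiver.subunits):
            out.add(
                InteractionRecord(
                    ProteinEntity([t]),
                    ProteinEntity([r]),
                    resource_name=rec.resource_name,
                    categories=rec.categories,
                    curation_refs=rec.curation_refs,
                )
            )
    return out


def filter_by_localisation(
    resource: Iterable[InteractionRecord],
    annotations: AnnotationTable,
    percentile_threshold: float = 51.0,
    qualifying: frozenset[str] = PLASMA_MEMBRANE_CATEGORIES,
) -> set[InteractionRecord]:
    """Keep records whose receiver is a plasma-membrane protein.

    Every receiver subunit must carry at least one qualifying localisation
    category *and* have a consensus percentile at or above the threshold.
    Receivers absent from the annotations fail the filter.
    """
    kept: set[InteractionRecord] = set()
    for rec in resource:
        ok = True
        for sub in rec.receiver.subunits:
            cats = annotations.categories_of(sub)
            if not cats & qualifying or annotations.percentile_of(sub) < percentile_threshold:
                ok = False
                break
        if ok:
            kept.add(rec)
    return kept


def filter_by_curation(
    resource: Iterable[InteractionRecord], min_refs: int = 1
) -> set[InteractionRecord]:
    """Keep records with at least ``min_refs`` literature references.

    Records without a stored count are dropped.
    """
    return {
        rec
        for rec in resource
        if rec.curation_refs is not None and rec.curation_refs >= min_refs
    }


# ---------------------------------------------------------------------------
# Cross-resource comparison
# ---------------------------------------------------------------------------

def _elements(records: Iterable[InteractionRecord], component: str) -> set:
    records = dissociate_complexes(records)
    if component == "interaction":
        return {rec.identity for rec in records}
    if component == "transmitter":
        return {rec.transmitter.name for rec in records}
    if component == "receiver":
        return {rec.receiver.name for rec in records}
    raise ValueError(f"unknown component {component!r}")


def overlap_stats(collection: ResourceCollection, component: str = "interaction") -> pd.DataFrame:
    """Unique vs shared elements per resource.

    An element is *unique* to a resource when no other resource in the
    collection contains it, and *shared* when at least one other does.
    ``pct_unique`` is reported on the 0-100 scale.
    """
    if len(collection) < 2:
        raise ValueError("overlap_stats needs at least two resources")
    sets = {name: _elements(recs, component) for name, recs in collection.resources.items()}
    rows = []
    for name, elems in sets.items():
        others: set = set()
        for other, oelems in sets.items():
            if other != name:
                others |= oelems
        n_unique = len(elems - others)
        n_shared = len(elems & others)
        total = n_unique + n_shared
        rows.append(
            {
                "resource": name,
                "n_unique": n_unique,
                "n_shared": n_shared,
                "pct_unique": 100.0 * n_unique / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("resource")


def pairwise_similarity(
    collection: ResourceCollection, component: str = "interaction"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Jaccard and asymmetric containment matrices between resources.

    Returns ``(jaccard, containment)`` where ``containment.loc[A, B]`` is the
    fraction of B's elements that are also present in A.  Similarity against
    an empty resource is defined as 0 (with a warning).
    """
    if len(collection) < 2:
        raise ValueError("pairwise_similarity needs at least two resources")
    names = collection.names()
    sets = {name: _elements(collection.resources[name], component) for name in names}
    empties = [n for n in names if not sets[n]]
    if empties:
        warnings.warn(f"empty resources in similarity computation: {empties}")
    jac = pd.DataFrame(0.0, index=names, columns=names)
    cont = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            jac.loc[a, b] = inter / union if union else 0.0
            cont.loc[a, b] = inter / len(sets[b]) if sets[b] else 0.0
        if sets[a]:
            jac.loc[a, a] = 1.0
    return jac, cont


def _in_category(
    element, component: str, category: str, annotations: AnnotationTable
) -> bool:
    if component == "interaction":
        t, r = element
        return category in annotations.categories_of(t) and category in annotations.categories_of(r)
    return category in annotations.categories_of(element)


def category_enrichment(
    collection: ResourceCollection,
    annotations: AnnotationTable,
    mode: str = "interaction",
) -> pd.DataFrame:
    """Fisher enrichment of each resource against the pooled background.

    For every (resource, category) pair a 2x2 table is built over the union
    of all resources' elements: membership in the resource vs membership in
    the category.  In interaction mode an interaction matches a category only
    when both its transmitter and receiver carry that category; elements may
    match several categories.  The odds ratio uses a Haldane +0.5 correction
    when any cell is zero, the p-value is the two-sided exact test on the raw
    counts, and FDR is Benjamini-Hochberg over all tests.  ``flag`` is the
    most stringent tier (0.05, 0.01, 0.001) at which |log2 OR| > 1 and
    FDR <= tier, or ``"none"``.
    """
    if mode not in {"interaction", "transmitter", "receiver"}:
        raise ValueError(f"unknown mode {mode!r}")
    sets = {name: _elements(recs, mode) for name, recs in collection.resources.items()}
    background: set = set()
    for s in sets.values():
        background |= s
    all_categories = sorted({c for cats in annotations.categories.values() for c in cats})

    # Pre-compute category membership over the background once.
    members = {
        cat: {e for e in background if _in_category(e, mode, cat, annotations)}
        for cat in all_categories
    }

    rows = []
    for name, elems in sets.items():
        rest = background - elems
        for cat in all_categories:
            cat_set = members[cat]
            a = len(elems & cat_set)
            b = len(elems) - a
            c = len(rest & cat_set)
            d = len(rest) - c
            table = np.array([[a, b], [c, d]])
            if table.min() == 0:
                odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                odds = (a * d) / (b * c)
            p = fisher_exact(table, alternative="two-sided")[1]
            rows.append(
                {"resource": name, "category": cat, "odds_ratio": odds, "p": p}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["flag"] = []
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    log2or = np.log2(out["odds_ratio"])
    flags = []
    for lo, fdr in zip(log2or, out["fdr"]):
        flag = "none"
        if abs(lo) > 1.0:
            for tier in ENRICHMENT_TIERS:
                if fdr <= tier:
                    flag = str(tier)
        flags.append(flag)
    out["flag"] = flags
    return out


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_resource_csv(path, resource_name: str | None = None) -> set[InteractionRecord]:
    """Read interaction records from a CSV.

    Expected columns: ``source_genesymbol``, ``target_genesymbol`` (subunits
    joined by ``_``); optional ``resource``, ``category`` (``;``-separated),
    ``curation_effort``.
    """
    df = pd.read_csv(path)
    required = {"source_genesymbol", "target_genesymbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"resource CSV missing columns: {sorted(missing)}")
    records: set[InteractionRecord] = set()
    for _, row in df.iterrows():
        cats: frozenset[str] = frozenset()
        if "category" in df.columns and pd.notna(row.get("category")):
            cats = frozenset(str(row["category"]).split(";"))
        refs = None
        if "curation_effort" in df.columns and pd.notna(row.get("curation_effort")):
            refs = int(row["curation_effort"])
        name = resource_name
        if name is None:
            name = str(row["resource"]) if "resource" in df.columns else ""
        records.add(
            InteractionRecord(
                ProteinEntity(str(row["source_genesymbol"])),
                ProteinEntity(str(row["target_genesymbol"])),
                resource_name=name,
                categories=cats,
                curation_refs=refs,
            )
        )
    return records


def write_resource_csv(records: Iterable[InteractionRecord], path) -> None:
    rows = [
        {
            "source_genesymbol": rec.transmitter.name,
            "target_genesymbol": rec.receiver.name,
            "resource": rec.resource_name,
            "category": ";".join(sorted(rec.categories)),
            "curation_effort": rec.curation_refs,
        }
        for rec in sorted(records, key=lambda r: r.identity)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotation_csv(path) -> AnnotationTable:
    """Read a gene annotation table.

    Columns: ``genesymbol``, ``category``, optional ``consensus_percentile``.
    One row per (gene, category); the percentile, when present, is per gene
    (the maximum over rows is used if they disagree).
    """
    df = pd.read_csv(path)
    required = {"genesymbol", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    cats: dict[str, set[str]] = {}
    perc: dict[str, float] = {}
    for _, row in df.iterrows():
        gene = str(row["genesymbol"]).strip().upper()
        cats.setdefault(gene, set()).add(str(row["category"]))
        if "consensus_percentile" in df.columns and pd.notna(row.get("consensus_percentile")):
            p = float(row["consensus_percentile"])
            perc[gene] = max(perc.get(gene, 0.0), p)
    return AnnotationTable({g: frozenset(c) for g, c in cats.items()}, perc)
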