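"""Species-level ecological-process indicators from scored effect traits.

Four multiplicative indicators estimate each taxon's potential
contribution to benthic processes mediating benthic-pelagic coupling:

* biomixing        mi  = AF x BM x MB x SD     (particle reworking)
* bioirrigation    ir  = VP x BM x BT x maxBD  (burrow ventilation)
* biodeposition    de  = BM x Su               (suspension-feeding transfer)
* deposit feeding  Dep = BM x De               (bulk sediment ingestion)

Each factor is a trait score: the affinity-weighted mean of the trait's
modality scores under the taxon's fuzzy profile (so a taxon split 50/50
between two modalities contributes the average of their scores; Su and De
are single-modality affinities of the feeding-type trait). A zero-scored
factor (immobile, no mixing activity, no bioconstruction) makes the
product zero. Raw products are rescaled across taxa to [0, 1] by the
observed maximum and binned into null / low / intermediate / high
categories at 0, 0.1 and 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import TraitCodebook, effect_codebook
from .tables import FuzzyTraitTable

INDICATORS = ("mi", "ir", "de", "Dep")
CATEGORY_EDGES = (0.1, 0.2)  # (0, .1] low, (.1, .2] intermediate, > .2 high

_FORMULAS = {
    "mi": ("AF", "BM", "MB", "SD"),
    "ir": ("VP", "BM", "BT", "maxBD"),
}


class MissingTraitError(ValueError):
    """A taxon lacks the trait block an indicator requires."""


@dataclass
class IndicatorScores:
    """Raw products, [0,1]-rescaled values and categories per taxon."""

    raw: pd.DataFrame        # taxa x indicators
    rescaled: pd.DataFrame
    category: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.raw.index)

    def write_csv(self, path) -> None:
        out = pd.concat(
            {"raw": self.raw, "rescaled": self.rescaled, "category": self.category},
            axis=1,
        )
        out.columns = [f"{a}_{b}" for a, b in out.columns]
        out.index.name = "taxon"
        out.to_csv(path)


def trait_score(taxon: str, trait_id: str, Q: FuzzyTraitTable,
                codebook: TraitCodebook | None = None,
                mode: str = "mean") -> float:
    """Score of one taxon on one effect trait.

    ``mode='mean'`` (default): affinity-weighted mean of the modality
    scores under the fuzzy profile. ``mode='max_affinity'``: score of the
    modality with the largest affinity (ties to the first listed).
    """
    codebook = codebook or effect_codebook()
    block = Q.block(trait_id).loc[taxon].astype(float)
    total = block.sum()
    if total <= 0:
        raise MissingTraitError(f"taxon {taxon!r} has no affinities for trait {trait_id!r}")
    scores = np.array([codebook[trait_id].score(m) for m in block.index], dtype=float)
    if mode == "mean":
        return float((block.to_numpy() / total) @ scores)
    if mode == "max_affinity":
        return float(scores[int(np.argmax(block.to_numpy()))])
    raise ValueError(f"unknown trait-score mode {mode!r}")


def _modality_affinity(taxon: str, trait_id: str, modality: str, Q: FuzzyTraitTable) -> float:
    block = Q.block(trait_id).loc[taxon].astype(float)
    total = block.sum()
    if total <= 0:
        raise MissingTraitError(f"taxon {taxon!r} has no affinities for trait {trait_id!r}")
    return float(block.get(modality, 0.0) / total)


def biomixing(taxon: str, Q: FuzzyTraitTable, codebook=None, mode="mean") -> float:
    """Raw biomixing product mi = AF x BM x MB x SD."""
    return float(np.prod([trait_score(taxon, t, Q, codebook, mode) for t in _FORMULAS["mi"]]))


def bioirrigation(taxon: str, Q: FuzzyTraitTable, codebook=None, mode="mean") -> float:
    """Raw bioirrigation product ir = VP x BM x BT x maxBD."""
    return float(np.prod([trait_score(taxon, t, Q, codebook, mode) for t in _FORMULAS["ir"]]))


def biodeposition(taxon: str, Q: FuzzyTraitTable, codebook=None, mode="mean") -> float:
    """Raw biodeposition product de = BM x Su (suspension-feeding affinity)."""
    return trait_score(taxon, "BM", Q, codebook, mode) * _modality_affinity(taxon, "FT", "Su", Q)


def deposit_feeding(taxon: str, Q: FuzzyTraitTable, codebook=None, mode="mean") -> float:
    """Raw deposit-feeding product Dep = BM x De (deposit-feeding affinity)."""
    return trait_score(taxon, "BM", Q, codebook, mode) * _modality_affinity(taxon, "FT", "De", Q)


_RAW_FUNCS = {"mi": biomixing, "ir": bioirrigation, "de": biodeposition, "Dep": deposit_feeding}


def categorize(rescaled: float) -> str:
    """Fig.-2 style bins: null (0), low (0,0.1], intermediate (0.1,0.2], high (>0.2)."""
    if rescaled == 0:
        return "null"
    if rescaled <= CATEGORY_EDGES[0]:
        return "low"
    if rescaled <= CATEGORY_EDGES[1]:
        return "intermediate"
    return "high"


def rescale_and_categorize(raw: pd.DataFrame) -> IndicatorScores:
    """Rescale raw products by the per-indicator maximum over taxa and bin.

    An all-zero indicator column stays zero (category "null" throughout).
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw indicator values must be >= 0")
    mx = raw.max(axis=0)
    rescaled = raw.div(mx.where(mx > 0, 1.0), axis=1)
    category = rescaled.map(categorize)
    return IndicatorScores(raw=raw, rescaled=rescaled, category=category)


def compute_indicators(Q: FuzzyTraitTable, codebook: TraitCodebook | None = None,
                       mode: str = "mean", taxa=None) -> IndicatorScores:
    """Raw, rescaled and categorized indicator scores for all documented taxa.

    Taxa missing any required effect-trait block are excluded (the
    exclusion list is available via ``FuzzyTraitTable.complete_taxa``).
    """
    codebook = codebook or effect_codebook()
    needed = sorted({t for f in _FORMULAS.values() for t in f} | {"FT"})
    if taxa is None:
        taxa = Q.complete_taxa([t for t in needed if t in Q.traits])
    raw = pd.DataFrame(
        {ind: [func(tx, Q, codebook, mode) for tx in taxa]
         for ind, func in _RAW_FUNCS.items()},
        index=pd.Index(taxa, name="taxon"),
    )
    return rescale_and_categorize(raw)
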