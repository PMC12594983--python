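"""Aggregation from species to community (site) level.

Three aggregation rules, matching how each quantity is interpreted:

* response traits — community weighted means (CWM) under *relative*
  densities: per site, the density-weighted average of the fuzzy trait
  profiles, so modality values of one trait sum to 1 per site;
* effect traits — *absolute* density weighting (unnormalized sums), as a
  denser community exerts a larger effect on ecosystem processes;
* indicators — community potentials: per site, the sum over taxa of
  density x rescaled species score, then rescaled across sites to [0,1];
* life-history groups — relative densities summed by group per site.

Densities default to the log10(x+1)-transformed values; raw-density mode
is available via ``use_raw``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .indicators import IndicatorScores
from .tables import AbundanceTable, FuzzyTraitTable

logger = logging.getLogger(__name__)


def _densities(L: AbundanceTable, use_raw: bool) -> pd.DataFrame:
    """Weights for aggregation: the table's values as-is (``use_raw``) or
    the log10(x+1)-transformed densities (default; applied if needed)."""
    if use_raw:
        return L.data
    if L.transform == "raw":
        L = L.log10p1()
    return L.data


def cwm_response(L: AbundanceTable, Q_response: FuzzyTraitTable,
                 use_raw: bool = False) -> pd.DataFrame:
    """Relative-density CWM of each response-trait modality per site.

    Empty sites (zero total density) are returned as NaN rows and logged.
    Per-trait modality values sum to 1 per non-empty site when every taxon
    has a complete block for that trait.
    """
    dens = _densities(L, use_raw)
    prof = Q_response.to_profile()
    taxa = [t for t in dens.columns if t in set(prof.taxa)]
    dens = dens[taxa]
    Qm = prof.data.loc[taxa]
    tot = dens.sum(axis=1)
    empty = tot <= 0
    if empty.any():
        logger.warning("empty site(s) in CWM: %s", list(dens.index[empty]))
    p = dens.div(tot.where(~empty, 1.0), axis=0)
    out = pd.DataFrame(p.to_numpy() @ Qm.to_numpy(), index=dens.index, columns=Qm.columns)
    out[empty] = np.nan
    return out


def cwm_effect(L: AbundanceTable, Q_effect: FuzzyTraitTable,
               use_raw: bool = False) -> pd.DataFrame:
    """Absolute community value of each effect-trait modality per site.

    Unnormalized by design: value(site, modality) = sum_i density_i x
    profile_i(modality); homogeneous of degree 1 in densities.
    """
    dens = _densities(L, use_raw)
    prof = Q_effect.to_profile()
    taxa = [t for t in dens.columns if t in set(prof.taxa)]
    dens = dens[taxa]
    Qm = prof.data.loc[taxa]
    return pd.DataFrame(dens.to_numpy() @ Qm.to_numpy(), index=dens.index, columns=Qm.columns)


def community_potential(L: AbundanceTable, scores: IndicatorScores,
                        use_raw: bool = False) -> pd.DataFrame:
    """Community potential per indicator: density-weighted score sums,
    rescaled across sites to [0, 1] by the observed maximum."""
    dens = _densities(L, use_raw)
    taxa = [t for t in dens.columns if t in set(scores.taxa)]
    raw = pd.DataFrame(
        dens[taxa].to_numpy() @ scores.rescaled.loc[taxa].to_numpy(),
        index=dens.index, columns=scores.rescaled.columns,
    )
    mx = raw.max(axis=0)
    return raw.div(mx.where(mx > 0, 1.0), axis=1)


def group_proportions(L: AbundanceTable, labels: pd.Series,
                      use_raw: bool = False, drop_unlabeled: bool = True) -> pd.DataFrame:
    """Per-site relative density summed by life-history group.

    Taxa without a label are dropped with a warning (``drop_unlabeled``)
    or raise. Proportions sum to 1 per non-empty site.
    """
    dens = _densities(L, use_raw)
    labels = labels.dropna()
    unlabeled = [t for t in dens.columns if t not in labels.index]
    if unlabeled:
        if not drop_unlabeled:
            raise ValueError(f"unlabeled taxa present: {unlabeled}")
        logger.warning("dropping %d unlabeled taxa from group proportions", len(unlabeled))
    taxa = [t for t in dens.columns if t in labels.index]
    dens = dens[taxa]
    tot = dens.sum(axis=1)
    p = dens.div(tot.where(tot > 0, 1.0), axis=0)
    out = p.T.groupby(labels.loc[taxa]).sum().T
    out[tot <= 0] = np.nan
    return out
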