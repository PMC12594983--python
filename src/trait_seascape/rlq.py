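"""Three-table RLQ co-inertia analysis and fourth-corner permutation inference.

RLQ links environment (R), abundance (L) and traits (Q): after separate
ordinations — CA of L, MCA of (discretized) R under the CA site weights,
FCA of Q under the CA species weights — the weighted cross-matrix

    tab = Z_R' D_site Z_L D_species Z_Q

is decomposed under the column metrics of the R- and Q-analyses. Its
total inertia measures the global trait-environment association carried
by the species distribution.

Inference follows the sequential permutation scheme: model 2 permutes
the site rows of L (breaking the R-L link), model 4 permutes the species
columns (breaking the L-Q link); an association is declared only when
both one-sided tests fall below the threshold, i.e. on the max of the
two p-values, with Benjamini-Hochberg control across the family of
trait x environment pairs. Per-pair fourth-corner statistics are
weighted pseudo-correlations (quantitative env) or correlation ratios
(categorical env) of trait modalities against descriptors through the
cell distribution of L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ordination import OrdinationResult, coa, fca, mca
from .tables import AbundanceTable, EnvironmentTable, FuzzyTraitTable

DEFAULT_N_PERM = 49_999


# ---------------------------------------------------------------------------
# RLQ decomposition
# ---------------------------------------------------------------------------

@dataclass
class RLQResult:
    eigenvalues: np.ndarray
    total_inertia: float
    env_scores: pd.DataFrame       # abiotic descriptor levels / columns
    trait_scores: pd.DataFrame     # trait modalities
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    row_metric: pd.Series          # weights of the R-analysis columns
    col_metric: pd.Series          # weights of the Q-analysis columns
    tab: pd.DataFrame

    @property
    def percent_inertia(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / self.total_inertia


def _check_aligned(a: pd.Series, b: pd.Series, what: str) -> None:
    if len(a) != len(b) or not np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-10):
        raise ValueError(f"{what} weights of the separate analyses are misaligned")


def rlq(ord_R: OrdinationResult, ord_L: OrdinationResult,
        ord_Q: OrdinationResult) -> RLQResult:
    """Co-inertia decomposition of the R-L-Q triple.

    The R- and Q-ordinations must have been run under the site and
    species weights of the CA of L (see ``weighted_reanalysis``).
    """
    _check_aligned(ord_R.row_weights, ord_L.row_weights, "site")
    _check_aligned(ord_Q.row_weights, ord_L.col_weights, "species")

    ZR = ord_R.tab.to_numpy()
    ZL = ord_L.tab.to_numpy()
    ZQ = ord_Q.tab.to_numpy()
    r = ord_L.row_weights.to_numpy()
    c = ord_L.col_weights.to_numpy()
    mR = ord_R.col_weights.to_numpy()
    mQ = ord_Q.col_weights.to_numpy()

    tab = ZR.T @ (ZL * r[:, None]) @ (ZQ * c[:, None])
    A = np.sqrt(mR)[:, None] * tab * np.sqrt(mQ)[None, :]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    eig = s**2
    keep = eig > 1e-12
    U, s, Vt, eig = U[:, keep], s[keep], Vt[keep], eig[keep]
    # canonical signs: largest |env coefficient| positive per axis
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            Vt[k] *= -1

    axes = [f"Axis{k+1}" for k in range(len(eig))]
    with np.errstate(divide="ignore", invalid="ignore"):
        smR = np.where(mR > 0, np.sqrt(mR), np.inf)
        smQ = np.where(mQ > 0, np.sqrt(mQ), np.inf)
    u_norm = U / smR[:, None]              # env coefficients, mR-normed
    v_norm = Vt.T / smQ[:, None]
    env_scores = u_norm * s
    trait_scores = v_norm * s
    site_scores = ZR @ (mR[:, None] * u_norm)
    species_scores = ZQ @ (mQ[:, None] * v_norm)

    total = float(np.sum(mR[:, None] * mQ[None, :] * tab**2))
    idxR, idxQ = ord_R.tab.columns, ord_Q.tab.columns
    return RLQResult(
        eigenvalues=eig,
        total_inertia=total,
        env_scores=pd.DataFrame(env_scores, index=idxR, columns=axes),
        trait_scores=pd.DataFrame(trait_scores, index=idxQ, columns=axes),
        site_scores=pd.DataFrame(site_scores, index=ord_R.tab.index, columns=axes),
        species_scores=pd.DataFrame(species_scores, index=ord_Q.tab.index, columns=axes),
        row_metric=pd.Series(mR, index=idxR),
        col_metric=pd.Series(mQ, index=idxQ),
        tab=pd.DataFrame(tab, index=idxR, columns=idxQ),
    )


def rlq_pipeline(R: EnvironmentTable, L: AbundanceTable, Q: FuzzyTraitTable,
                 n_classes: int = 3) -> tuple[RLQResult, OrdinationResult,
                                              OrdinationResult, OrdinationResult]:
    """CA of L, weighted MCA of R and weighted FCA of Q, then RLQ."""
    ord_L = coa(L.data)
    ord_R = mca(EnvironmentTable(R.data.loc[ord_L.tab.index]),
                row_weights=ord_L.row_weights, n_classes=n_classes)
    ord_Q = fca(Q.subset_taxa(list(ord_L.tab.columns)),
                row_weights=ord_L.col_weights)
    return rlq(ord_R, ord_L, ord_Q), ord_R, ord_L, ord_Q


# ---------------------------------------------------------------------------
# Fourth-corner statistics
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    mean = w @ X
    Z = X - mean
    sd = np.sqrt(w @ Z**2)
    sd = np.where(sd > 0, sd, np.inf)
    return Z / sd


@dataclass
class FourthCornerResult:
    """Per trait-modality x descriptor association table."""

    stat: pd.DataFrame          # env descriptors x trait modalities
    stat_type: pd.Series        # per env descriptor: "r" | "eta2"
    p_model2: pd.DataFrame
    p_model4: pd.DataFrame
    p_combined: pd.DataFrame
    p_fdr: pd.DataFrame
    n_perm: int
    seed: int
    alpha: float = 0.05
    modality_trait: pd.Series = field(default_factory=pd.Series)

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_fdr <= self.alpha


class _FourthCornerEngine:
    """Precomputed pieces for fast permutation of per-pair statistics."""

    def __init__(self, R: EnvironmentTable, L: AbundanceTable, Q: FuzzyTraitTable):
        dens = L.data.to_numpy(dtype=float)
        if dens.sum() <= 0:
            raise ValueError("abundance table has zero grand total")
        self.P = dens / dens.sum()
        self.r = self.P.sum(axis=1)
        self.c = self.P.sum(axis=0)

        prof = Q.to_profile()
        qdat = prof.data.loc[list(L.data.columns)]
        self.modality_trait = pd.Series([t for t, _ in qdat.columns],
                                        index=[f"{t}__{m}" for t, m in qdat.columns])
        self.Y = qdat.to_numpy(dtype=float)
        self.modalities = list(self.modality_trait.index)

        quant = R.quantitative
        self.quant_cols = list(quant.columns)
        self.X = quant.loc[L.data.index].to_numpy(dtype=float)
        self.cat_cols = list(R.categorical.columns)
        self.G = {col: pd.get_dummies(R.categorical[col]).to_numpy(dtype=float)
                  for col in self.cat_cols}
        self.env_cols = self.quant_cols + self.cat_cols

    def stats(self, site_perm: np.ndarray | None = None,
              species_perm: np.ndarray | None = None) -> np.ndarray:
        """(env descriptors x modalities) statistic matrix under a permutation."""
        X = self.X if site_perm is None else self.X[site_perm]
        Y = self.Y if species_perm is None else self.Y[species_perm]
        Ys = _standardize(Y, self.c)
        out = np.empty((len(self.env_cols), Ys.shape[1]))
        if self.quant_cols:
            Xs = _standardize(X, self.r)
            out[: len(self.quant_cols)] = Xs.T @ self.P @ Ys
        for i, col in enumerate(self.cat_cols):
            G = self.G[col] if site_perm is None else self.G[col][site_perm]
            wg = self.r @ G
            M = G.T @ self.P @ Ys  # level x modality cell sums of standardized trait
            with np.errstate(divide="ignore", invalid="ignore"):
                eta2 = np.where(wg[:, None] > 0, M**2 / np.where(wg[:, None] > 0, wg[:, None], 1.0), 0.0).sum(axis=0)
            out[len(self.quant_cols) + i] = eta2
        return out


def fourth_corner(R: EnvironmentTable, L: AbundanceTable, Q: FuzzyTraitTable,
                  n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                  alpha: float = 0.05, two_sided: bool = True,
                  fdr_order: str = "fdr_after_max") -> FourthCornerResult:
    """Fourth-corner tests of every descriptor x trait-modality pair.

    p-values use the add-one permutation estimator (r+1)/(n+1); signed
    statistics are tested two-sided by default, correlation ratios are
    always upper-tailed. Model 2 permutes the site rows of L, model 4
    the species columns; the same permutation is shared by all pairs
    within one iteration.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eng = _FourthCornerEngine(R, L, Q)
    obs = eng.stats()
    n_quant = len(eng.quant_cols)
    mag = np.abs(obs) if two_sided else obs
    mag[n_quant:] = obs[n_quant:]  # eta2: upper tail regardless

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4C]))
    counts = {2: np.zeros_like(obs), 4: np.zeros_like(obs)}
    n_sites, n_species = eng.P.shape
    for _ in range(n_perm):
        s2 = eng.stats(site_perm=rng.permutation(n_sites))
        s4 = eng.stats(species_perm=rng.permutation(n_species))
        for model, sp in ((2, s2), (4, s4)):
            pm = np.abs(sp) if two_sided else sp
            pm[n_quant:] = sp[n_quant:]
            counts[model] += pm >= mag - 1e-12
    pvals = {m: (counts[m] + 1.0) / (n_perm + 1.0) for m in (2, 4)}

    idx = pd.Index(eng.env_cols, name="descriptor")
    cols = pd.Index(eng.modalities, name="modality")
    stat = pd.DataFrame(obs, index=idx, columns=cols)
    p2 = pd.DataFrame(pvals[2], index=idx, columns=cols)
    p4 = pd.DataFrame(pvals[4], index=idx, columns=cols)
    p_comb, p_fdr = combine_and_adjust(p2, p4, order=fdr_order)
    stat_type = pd.Series(["r"] * n_quant + ["eta2"] * len(eng.cat_cols), index=idx)
    return FourthCornerResult(stat=stat, stat_type=stat_type, p_model2=p2,
                              p_model4=p4, p_combined=p_comb, p_fdr=p_fdr,
                              n_perm=n_perm, seed=seed, alpha=alpha,
                              modality_trait=eng.modality_trait)


def combine_and_adjust(p2: pd.DataFrame, p4: pd.DataFrame,
                       order: str = "fdr_after_max") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential max-p combination and BH false-discovery-rate adjustment.

    ``order='fdr_after_max'`` (default): combine first, then BH across
    the whole pair family. ``'fdr_before_max'``: BH within each model,
    then combine.
    """
    if not p2.index.equals(p4.index) or not p2.columns.equals(p4.columns):
        raise ValueError("the two model p-value tables cover different pairs")
    p_comb = np.maximum(p2, p4)
    if order == "fdr_after_max":
        flat = p_comb.to_numpy().ravel()
        adj = multipletests(flat, method="fdr_bh")[1]
        p_fdr = pd.DataFrame(adj.reshape(p_comb.shape), index=p_comb.index,
                             columns=p_comb.columns)
    elif order == "fdr_before_max":
        adj2 = multipletests(p2.to_numpy().ravel(), method="fdr_bh")[1]
        adj4 = multipletests(p4.to_numpy().ravel(), method="fdr_bh")[1]
        p_fdr = pd.DataFrame(np.maximum(adj2, adj4).reshape(p_comb.shape),
                             index=p_comb.index, columns=p_comb.columns)
    else:
        raise ValueError(f"unknown FDR order {order!r}")
    return p_comb, p_fdr


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper, kept for clarity)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Global RLQ significance (total inertia under models 2 and 4)
# ---------------------------------------------------------------------------

class _RLQInertiaEngine:
    """Fast recomputation of RLQ total inertia under permutations.

    Matches the full pipeline (CA of L, weighted MCA of R, weighted FCA
    of Q): model-2 permutations re-pair R rows with L rows, model-4
    permutations re-pair Q rows with L columns; weights and centerings
    are recomputed per permutation exactly as the pipeline would.
    """

    def __init__(self, R: EnvironmentTable, L: AbundanceTable, Q: FuzzyTraitTable,
                 n_classes: int = 3):
        dens = L.data.to_numpy(dtype=float)
        keep_r = dens.sum(axis=1) > 0
        keep_c = dens.sum(axis=0) > 0
        dens = dens[np.ix_(keep_r, keep_c)]
        self.P = dens / dens.sum()
        self.r = self.P.sum(axis=1)
        self.c = self.P.sum(axis=0)
        # R side: MCA indicator profiles (rows sum to 1)
        mres = mca(EnvironmentTable(R.data.loc[L.data.index[keep_r]]),
                   n_classes=n_classes)
        self.XR = (mres.tab.to_numpy() + 1.0) * mres.col_weights.to_numpy()[None, :]
        # Q side: fuzzy profiles / n_traits (rows sum to 1)
        prof = Q.to_profile()
        qdat = prof.data.loc[list(L.data.columns[keep_c])]
        self.XQ = qdat.to_numpy(dtype=float) / len(prof.traits)

    def inertia(self, site_perm=None, species_perm=None) -> float:
        XR = self.XR if site_perm is None else self.XR[site_perm]
        XQ = self.XQ if species_perm is None else self.XQ[species_perm]
        cwR = self.r @ XR
        cwQ = self.c @ XQ
        ZR = XR / np.where(cwR > 0, cwR, np.inf)[None, :] - 1.0
        ZQ = XQ / np.where(cwQ > 0, cwQ, np.inf)[None, :] - 1.0
        tab = ZR.T @ self.P @ ZQ
        return float(np.sum(cwR[:, None] * cwQ[None, :] * tab**2))


@dataclass
class GlobalTestResult:
    inertia: float
    p_model2: float
    p_model4: float
    n_perm: int
    seed: int

    @property
    def p_combined(self) -> float:
        return max(self.p_model2, self.p_model4)


def rlq_global_test(R: EnvironmentTable, L: AbundanceTable, Q: FuzzyTraitTable,
                    n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                    n_classes: int = 3) -> GlobalTestResult:
    """Permutation test of the RLQ total inertia under models 2 and 4."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eng = _RLQInertiaEngine(R, L, Q, n_classes=n_classes)
    obs = eng.inertia()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x52]))
    n_sites, n_species = eng.P.shape
    ge2 = ge4 = 0
    for _ in range(n_perm):
        if eng.inertia(site_perm=rng.permutation(n_sites)) >= obs - 1e-12:
            ge2 += 1
        if eng.inertia(species_perm=rng.permutation(n_species)) >= obs - 1e-12:
            ge4 += 1
    return GlobalTestResult(inertia=obs, p_model2=(ge2 + 1) / (n_perm + 1),
                            p_model4=(ge4 + 1) / (n_perm + 1),
                            n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Preliminary screening and axis-correlation tests
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    kept_descriptors: list[str]
    kept_traits: list[str]
    dropped_descriptors: list[str]
    dropped_traits: list[str]
    best_p: pd.DataFrame


def screen_variables(R: EnvironmentTable, L: AbundanceTable, Q: FuzzyTraitTable,
                     alpha_screen: float = 0.05, n_perm: int = 999, seed: int = 0,
                     ) -> tuple[EnvironmentTable, FuzzyTraitTable, ScreeningReport]:
    """Retain descriptors and traits with a promising preliminary signal.

    A descriptor is kept when its best (minimum) unadjusted combined
    fourth-corner p-value over all trait modalities is <= alpha_screen;
    a trait is kept when any of its modalities reaches that bar against
    any descriptor. ``alpha_screen=1`` is the identity.
    """
    fc = fourth_corner(R, L, Q, n_perm=n_perm, seed=seed)
    best_env = fc.p_combined.min(axis=1)
    keep_env = list(best_env.index[best_env <= alpha_screen])
    by_trait = fc.p_combined.T.groupby(fc.modality_trait).min().min(axis=1)
    keep_traits = list(by_trait.index[by_trait <= alpha_screen])
    if not keep_env or not keep_traits:
        raise ValueError(
            f"screening at alpha={alpha_screen} retained nothing; increase alpha_screen")
    report = ScreeningReport(
        kept_descriptors=keep_env,
        kept_traits=keep_traits,
        dropped_descriptors=[v for v in best_env.index if v not in keep_env],
        dropped_traits=[t for t in by_trait.index if t not in keep_traits],
        best_p=fc.p_combined,
    )
    R2 = EnvironmentTable(R.data[keep_env])
    Q2 = Q.subset_traits(keep_traits)
    return R2, Q2, report


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    xc = x - w @ x
    yc = y - w @ y
    denom = np.sqrt((w @ xc**2) * (w @ yc**2))
    return float((w @ (xc * yc)) / denom) if denom > 0 else 0.0


def _correlation_ratio(codes: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """eta^2 of y across the groups given by codes, under weights w."""
    w = w / w.sum()
    yc = y - w @ y
    tot = w @ yc**2
    if tot <= 0:
        return 0.0
    eta = 0.0
    for g in np.unique(codes):
        sel = codes == g
        wg = w[sel].sum()
        if wg > 0:
            eta += wg * (w[sel] @ yc[sel] / wg) ** 2
    return float(eta / tot)


def axis_correlation_tests(result: RLQResult, R: EnvironmentTable,
                           Q: FuzzyTraitTable, n_perm: int = 999, seed: int = 0,
                           n_axes: int = 2) -> pd.DataFrame:
    """Permutation tests of each RLQ axis against individual variables.

    Environmental descriptors are tested against site scores under the
    site weights (weighted correlation, or correlation ratio for
    factors); trait modalities against species scores under the species
    weights. Returns a tidy frame with one row per (axis, variable).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA7]))
    site_w = np.full(len(result.site_scores), 1.0)
    # site/species weights: recover from the metrics of the separate analyses
    rows = []
    n_axes = min(n_axes, result.site_scores.shape[1])
    for ax in range(n_axes):
        s_site = result.site_scores.iloc[:, ax].to_numpy()
        s_sp = result.species_scores.iloc[:, ax].to_numpy()
        for col in R.quantitative.columns:
            x = R.data.loc[result.site_scores.index, col].to_numpy(dtype=float)
            obs = _weighted_corr(x, s_site, site_w)
            ge = sum(abs(_weighted_corr(x[rng.permutation(len(x))], s_site, site_w))
                     >= abs(obs) - 1e-12 for _ in range(n_perm))
            rows.append(("env", col, f"Axis{ax+1}", obs, "r", (ge + 1) / (n_perm + 1)))
        for col in R.categorical.columns:
            codes = pd.Categorical(R.data.loc[result.site_scores.index, col]).codes
            obs = _correlation_ratio(codes, s_site, site_w)
            ge = sum(_correlation_ratio(codes[rng.permutation(len(codes))], s_site, site_w)
                     >= obs - 1e-12 for _ in range(n_perm))
            rows.append(("env", col, f"Axis{ax+1}", obs, "eta2", (ge + 1) / (n_perm + 1)))
        prof = Q.to_profile().data
        sp_w = np.full(len(s_sp), 1.0)
        for (trait, mod) in prof.columns:
            key = f"{trait}__{mod}"
            y = prof[(trait, mod)].loc[result.species_scores.index].to_numpy(dtype=float)
            obs = _weighted_corr(y, s_sp, sp_w)
            ge = sum(abs(_weighted_corr(y[rng.permutation(len(y))], s_sp, sp_w))
                     >= abs(obs) - 1e-12 for _ in range(n_perm))
            rows.append(("trait", key, f"Axis{ax+1}", obs, "r", (ge + 1) / (n_perm + 1)))
    return pd.DataFrame(rows, columns=["side", "variable", "axis", "stat",
                                       "stat_type", "p"])
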