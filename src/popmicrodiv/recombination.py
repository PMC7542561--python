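"""Recombination inference from the synonymous-site correlation profile.

For every pair of 4-fold degenerate sites jointly covered by a single read at
distance ``l``, the profile accumulates the product of reference-mismatch
indicators; ``d(l)`` is the probability that both sites differ from the
reference, and ``d_sample`` the single-site synonymous diversity.  In a
population whose lineages carry heterogeneous divergence, linked sites share
one divergence draw and ``d(l)`` exceeds ``d_sample**2``; recombination
re-assorts ancestry along the genome and pushes ``d(l)`` back towards the
independence product.  The fitted model treats ancestry as a
"most-recent-event" fragment mosaic:

    d(l) = ds^2 * (1 + V * S(l))
    S(l) = exp(-lam*(2-kappa)) + kappa/(2-kappa) * (1 - exp(-lam*(2-kappa)))
    kappa = exp(-l / fbar)

where ``S(l)`` is the probability that two sites at distance ``l`` share
ancestry, ``lam`` is the expected number of recombination fragments covering a
site (the recombination coverage intensity), ``fbar`` the mean fragment
length, and ``V`` the relative excess of squared over squared-mean lineage
divergence (V = 1 for exponential pair-coalescence times).  In this model the
ratio of recombination-imported to mutational substitutions is ``lam`` itself,
so gamma/mu = lam and the recombination coverage is c = 1 - exp(-lam):
c = 0 is clonal evolution, c -> 1 a population that has recombined nearly its
whole genome.

Fragment lengths beyond the within-read window are not identifiable, so
``fbar_hat`` is capped at twice the maximum pair distance; without that cap a
flat (clonal) profile could be fit equally well by an arbitrarily large
fragment length and an arbitrary ``lam``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import genetics
from .recruitment import AlignmentSet
from .seqio import AnnotatedGenome

logger = logging.getLogger("popmicrodiv")


def synonymous_site_mask(genome: AnnotatedGenome) -> np.ndarray:
    """Genome positions (sorted) where every single-base change is synonymous
    (4-fold degenerate third codon positions); masked regions excluded."""
    out = []
    masked = genome.mask_array()
    for gene in genome.genes:
        pos = gene.codon_positions()  # (n_codons, 3) gene-frame
        ci = genome.gene_ref_codons(gene)
        ff = genetics.FOURFOLD_POS64[ci]  # (n_codons, 3) in gene frame
        sites = pos[ff]
        out.append(sites[~masked[sites]])
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(out)).astype(np.int64)


@dataclass
class CorrelationProfile:
    """d(l) over within-read synonymous site pairs, plus the l=0 diversity."""

    distances: np.ndarray  # l values with at least one pair
    d: np.ndarray
    n_pairs: np.ndarray
    d_sample: float
    n_sites_observed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"l": self.distances, "d": self.d, "n_pairs": self.n_pairs})


def correlation_profile(
    aln: AlignmentSet,
    genome: AnnotatedGenome,
    mask: np.ndarray | None = None,
    max_l: int = 140,
) -> CorrelationProfile:
    """Accumulate mismatch-product statistics over all jointly covered
    4-fold-site pairs within single reads."""
    if mask is None:
        mask = synonymous_site_mask(genome)
    mask = np.asarray(mask, dtype=np.int64)
    if mask.size == 0:
        raise ValueError("synonymous site mask is empty")
    if len(aln) and max_l >= int(aln.span.max()):
        raise ValueError("max_l must be smaller than the read (alignment) length")

    ref = genome.codes
    num = np.zeros(max_l + 1, dtype=np.int64)
    den = np.zeros(max_l + 1, dtype=np.int64)
    site_obs = 0
    site_mis = 0
    triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    starts = aln.ref_start
    offs = aln.offsets
    spans = aln.span
    bases = aln.bases
    lo = np.searchsorted(mask, starts)
    hi = np.searchsorted(mask, starts + spans)
    for i in range(len(aln)):
        a, b = int(lo[i]), int(hi[i])
        m = b - a
        if m == 0:
            continue
        sites = mask[a:b]
        col = sites - starts[i] + offs[i]
        x = bases[col] != ref[sites]
        site_obs += m
        site_mis += int(x.sum())
        if m < 2:
            continue
        if m not in triu_cache:
            triu_cache[m] = np.triu_indices(m, k=1)
        iu, ju = triu_cache[m]
        dist = sites[ju] - sites[iu]
        ok = dist <= max_l
        np.add.at(den, dist[ok], 1)
        both = x[iu] & x[ju]
        sel = ok & both
        if sel.any():
            np.add.at(num, dist[sel], 1)

    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    keep = np.flatnonzero(den > 0)
    keep = keep[keep > 0]
    return CorrelationProfile(
        distances=keep,
        d=d[keep],
        n_pairs=den[keep],
        d_sample=site_mis / site_obs if site_obs else float("nan"),
        n_sites_observed=site_obs,
    )


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------

@dataclass
class RecombinationEstimate:
    gamma_over_mu: float
    c: float
    thetas: float            # per-site synonymous diversity (mutational divergence)
    phis: float              # recombinational divergence rate, gamma_over_mu * thetas / fbar
    fbar_hat: float
    linkage_excess: float    # fitted V
    fit_residual: float
    converged: bool
    ci: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in vars(self).items() if k != "ci"}
        return pd.DataFrame([d])


def _shared_ancestry(l: np.ndarray, lam: float, fbar: float) -> np.ndarray:
    kappa = np.exp(-l / fbar)
    a = np.exp(-lam * (2.0 - kappa))
    return a + kappa / (2.0 - kappa) * (1.0 - a)


def profile_model(
    l: np.ndarray, ds: float, V: float, lam: float, fbar: float, eps: float = 0.0
) -> np.ndarray:
    """Expected d(l); ``eps`` is the probability that two sites in different
    fragments coincide in ancestry anyway (finite donor pools leave a small
    long-range floor that would otherwise masquerade as clonal signal)."""
    s = _shared_ancestry(np.asarray(l, dtype=float), lam, fbar)
    return ds * ds * (1.0 + V * ((1.0 - eps) * s + eps))


def bin_profile(profile: CorrelationProfile, width: int = 10) -> CorrelationProfile:
    """Pool the profile into distance bins of ``width`` bp (pair-count
    weighted); individual distances carry too few doubly-mutated pairs to be
    stable on their own."""
    if width <= 1:
        return profile
    grp = profile.distances // width
    uniq = np.unique(grp)
    n = np.array([profile.n_pairs[grp == g].sum() for g in uniq], dtype=np.int64)
    num = np.array([(profile.d * profile.n_pairs)[grp == g].sum() for g in uniq])
    lmid = np.array([
        np.average(profile.distances[grp == g], weights=profile.n_pairs[grp == g])
        for g in uniq
    ])
    return CorrelationProfile(lmid, num / n, n, profile.d_sample, profile.n_sites_observed)


def fit_recombination(
    profile: CorrelationProfile,
    n_boot: int = 0,
    seed: int = 0,
    bin_width: int = 10,
) -> RecombinationEstimate:
    """Fit the mosaic-ancestry model to a (binned) correlation profile by
    bounded, pair-count-weighted least squares (multi-start on lam)."""
    if profile.distances.size < 10:
        raise ValueError("profile needs at least 10 distance points to fit")
    binned = bin_profile(profile, bin_width)
    l = binned.distances.astype(float)
    d = binned.d
    w = np.sqrt(binned.n_pairs.astype(float))
    ds = binned.d_sample
    if not np.isfinite(ds) or ds <= 0 or d.sum() == 0:
        logger.warning("fit_recombination: no synonymous diversity; clonal by construction")
        return RecombinationEstimate(0.0, 0.0, float(ds) if np.isfinite(ds) else 0.0,
                                     0.0, float("nan"), 0.0, 0.0, True)

    lmax = float(l.max())
    # chained fragment copying shortens the effective same-ancestry blocks, so
    # the decay scale may fall well below the nominal fragment length; but
    # fragments beyond the window are unidentifiable, and extremely short ones
    # would let a one-bin bump mimic any flat level
    f_lo, f_hi = 25.0, 2.0 * lmax
    scale = ds * ds

    def resid(p):
        V, lam, fbar, eps = p
        return (profile_model(l, ds, V, lam, fbar, eps) - d) * w / scale

    v0 = float(np.clip(d[: max(3, len(d) // 10)].mean() / scale - 1.0, 0.05, 10.0))
    best = None
    for lam0 in (0.05, 0.5, 2.0, 8.0):
        for f0 in (max(f_lo, lmax / 4.0), lmax):
            try:
                # eps is capped at the donor-coincidence floor of a
                # many-lineage pool (1/(n-1) for n >~ 35); a looser cap would
                # let eps swallow the clonal-survival floor that identifies lam
                res = least_squares(
                    resid, x0=[v0, lam0, f0, 0.01],
                    bounds=([0.0, 0.0, f_lo, 0.0], [50.0, 50.0, f_hi, 0.03]),
                    method="trf",
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("recombination fit failed from every start")
    V, lam, fbar, eps = best.x
    rms = float(np.sqrt(2.0 * best.cost / len(l)))

    # The curve fit pins V, fbar and eps well, but lam rides a ridge: above
    # lam ~ 2 the (lam, fbar) family shadows any moderate-lam curve except in
    # the long-range linkage floor.  When the window resolves the fragment
    # scale, re-derive lam by matching the observed ratio of long-range to
    # short-range linkage excess — a strictly decreasing 1-D function of lam
    # in which the overall excess scale V cancels.
    short = l <= lmax / 7.0
    tail = l >= 0.65 * lmax
    if fbar <= lmax / 3.0 and short.any() and tail.any():
        excess = d / scale - 1.0
        w2 = w * w
        e_short = float(np.average(excess[short], weights=w2[short]))
        e_tail = float(np.average(excess[tail], weights=w2[tail]))
        if e_short > 0:
            from scipy.optimize import brentq

            r_obs = float(np.clip(e_tail / e_short, 1e-6, 1.0))

            def ratio(lam_):
                s_s = np.average(_shared_ancestry(l[short], lam_, fbar), weights=w2[short])
                s_t = np.average(_shared_ancestry(l[tail], lam_, fbar), weights=w2[tail])
                return ((1 - eps) * s_t + eps) / ((1 - eps) * s_s + eps)

            lam_hi = 20.0
            if ratio(lam_hi) >= r_obs:
                lam = lam_hi  # floor at/below the irreducible residue: saturated
            elif ratio(0.0) <= r_obs:
                lam = 0.0
            else:
                lam = float(brentq(lambda x: ratio(x) - r_obs, 0.0, lam_hi, xtol=1e-4))

    # guard against fitting decay to noise: a clonal (flat) profile is the
    # nested lam=0 model; keep the decay only if it improves the fit
    # significantly (F-test on the weighted residuals, 3 extra parameters)
    flat_v = float(np.clip(np.average(d, weights=w * w) / scale - 1.0, 0.0, 50.0))
    ssr_flat = float(np.sum(((ds * ds * (1.0 + flat_v) - d) * w / scale) ** 2))
    ssr_full = float(2.0 * best.cost)
    dof = len(l) - 4
    if dof > 0 and ssr_full > 0:
        from scipy.stats import f as f_dist

        fstat = ((ssr_flat - ssr_full) / 3.0) / (ssr_full / dof)
        if fstat < 0 or f_dist.sf(fstat, 3, dof) > 0.05:
            V, lam, fbar = flat_v, 0.0, float("inf")
            rms = float(np.sqrt(ssr_flat / len(l)))

    ci: dict = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        lams, cs = [], []
        for _ in range(n_boot):
            idx = np.sort(rng.integers(0, len(l), size=len(l)))
            p = CorrelationProfile(binned.distances[idx], d[idx], binned.n_pairs[idx],
                                   ds, binned.n_sites_observed)
            try:
                est = fit_recombination(p, n_boot=0, bin_width=1)
            except ValueError:
                continue
            lams.append(est.gamma_over_mu)
            cs.append(est.c)
        if lams:
            ci = {
                "gamma_over_mu": tuple(np.percentile(lams, [2.5, 97.5])),
                "c": tuple(np.percentile(cs, [2.5, 97.5])),
            }

    if not best.success:
        logger.warning("fit_recombination: optimizer did not converge (residual %.3g)", rms)
    return RecombinationEstimate(
        gamma_over_mu=float(lam),
        c=float(1.0 - np.exp(-lam)),
        thetas=float(ds),
        phis=float(lam * ds / fbar),
        fbar_hat=float(fbar),
        linkage_excess=float(V),
        fit_residual=rms,
        converged=bool(best.success),
        ci=ci,
    )
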