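"""Site-wise Bayesian dN/dS estimation and codon-based Z-tests.

The sampler targets a composite likelihood in the PAC (product of
approximate conditionals) family: sequences are visited in random
orderings and each contributes a pairwise NY98 transition term against
its predecessor; the per-ordering log-likelihoods are averaged.  Because
terms factorise over codon columns, per-site selection coefficients
(omega) can be Gibbs-sampled exactly on a log-spaced grid while the
shared divergence (mu) and transition/transversion ratio (kappa) move by
Metropolis steps.  This is a deliberate desk-scale simplification of the
full omegaMap machinery: the omega model is "independent" (no smoothing
blocks) and recombination is handled separately.

Codons containing gaps, ambiguity or stop codons are treated as missing
data and dropped from the pairwise terms of the affected sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .codons import codon_indices, ny98_rate_matrix
from .diversity import _usable_codon, codon_pair_differences, codon_sites
from .seq_model import Alignment


@dataclass
class McmcSettings:
    """Defaults mirror the study protocol; scale down for desk runs."""

    iterations: int = 500_000
    burn_in: int = 50_000
    thinning: int = 100
    codon_frequency_model: str = "1/61"
    n_orderings: int = 10
    omega_model: str = "independent"
    rho_model: str = "none"
    seed: int = 0
    omega_grid_size: int = 40
    omega_min: float = 0.01
    omega_max: float = 100.0
    mu_prior_rate: float = 1.0     # exponential prior rates
    kappa_prior_rate: float = 0.5

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.omega_model != "independent":
            raise ValueError("only the independent omega model is implemented")

    def omega_grid(self) -> np.ndarray:
        return np.geomspace(self.omega_min, self.omega_max, self.omega_grid_size)


@dataclass(frozen=True)
class SitePosterior:
    codon_site: int
    omega_mean: float
    hpd_low: float
    hpd_high: float
    pp_positive: float
    is_pbr: bool = False
    pbr_distance: int = -1

    def __post_init__(self):
        if not 0.0 <= self.pp_positive <= 1.0:
            raise ValueError("pp_positive outside [0, 1]")
        if self.hpd_low > self.hpd_high:
            raise ValueError("hpd_low > hpd_high")


@dataclass
class OmegaRun:
    """Posterior summaries plus raw retained samples of one MCMC run."""

    posteriors: list[SitePosterior]
    omega_samples: np.ndarray      # (n_samples, n_sites)
    mu_samples: np.ndarray
    kappa_samples: np.ndarray
    settings: McmcSettings
    accept_mu: float = 0.0
    accept_kappa: float = 0.0


def _pair_terms(codes: np.ndarray, n_orderings: int, rng: np.random.Generator):
    """Unique (prev, curr) codon pairs with weights per site.

    Returns flat arrays (pair_i, pair_j, site_id, weight) suitable for
    np.bincount accumulation of per-site log-likelihoods.
    """
    n, S = codes.shape
    counts: dict[tuple[int, int, int], float] = {}
    for _ in range(n_orderings):
        order = rng.permutation(n)
        for a, b in zip(order[:-1], order[1:]):
            ca, cb = codes[a], codes[b]
            for s in range(S):
                i, j = ca[s], cb[s]
                if i < 0 or j < 0:
                    continue
                key = (s, i, j)
                counts[key] = counts.get(key, 0.0) + 1.0
    if not counts:
        raise ValueError("alignment contains no usable codon pairs")
    keys = sorted(counts)
    site_id = np.array([k[0] for k in keys], dtype=np.int64)
    pair_i = np.array([k[1] for k in keys], dtype=np.int64)
    pair_j = np.array([k[2] for k in keys], dtype=np.int64)
    weight = np.array([counts[k] for k in keys]) / n_orderings
    return pair_i, pair_j, site_id, weight


class _GridLikelihood:
    """Per-site log-likelihood table over the omega grid."""

    def __init__(self, codes: np.ndarray, grid: np.ndarray,
                 n_orderings: int, rng: np.random.Generator):
        self.grid = grid
        self.n_sites = codes.shape[1]
        (self.pi, self.pj, self.site_id, self.weight) = _pair_terms(
            codes, n_orderings, rng)
        self._eig_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        # entries are sorted by site, so per-site sums are segment sums
        present, starts = np.unique(self.site_id, return_index=True)
        self._present = present
        self._starts = starts

    def _eigs(self, kappa: float) -> tuple[np.ndarray, np.ndarray]:
        cached = self._eig_cache.get(kappa)
        if cached is None:
            qs = np.stack([ny98_rate_matrix(kappa, float(w)) for w in self.grid])
            cached = np.linalg.eigh(qs)        # batched over the grid
            if len(self._eig_cache) > 3:       # keep current + proposal
                self._eig_cache.clear()
            self._eig_cache[kappa] = cached
        return cached

    def table(self, mu: float, kappa: float) -> np.ndarray:
        """(grid, n_sites) array of per-site log-likelihood contributions."""
        w, v = self._eigs(kappa)
        ew = np.exp(w * mu)                                     # (G, 61)
        p = np.einsum("gij,gj,gkj->gik", v, ew, v)              # (G, 61, 61)
        np.clip(p, 1e-300, None, out=p)
        logp = np.log(p)
        contrib = logp[:, self.pi, self.pj] * self.weight       # (G, entries)
        sums = np.add.reduceat(contrib, self._starts, axis=1)
        out = np.zeros((len(self.grid), self.n_sites))
        out[:, self._present] = sums
        return out


def _alignment_codes(aln: Alignment) -> np.ndarray:
    codes = [codon_indices(seq) for _, seq in aln.records]
    return np.vstack(codes)


def _hpd(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    x = np.sort(samples)
    n = len(x)
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + k])


def site_omega_mcmc(aln: Alignment, settings: McmcSettings,
                    pbr_sites: list[int] | None = None) -> OmegaRun:
    """Sample per-site omega posteriors under the PAC composite likelihood.

    Requires >= 3 sequences.  Returns posterior summaries together with
    the retained (post burn-in, thinned) raw samples, so every reported
    quantity can be re-derived from the dump.
    """
    if len(aln) < 3:
        raise ValueError("site_omega_mcmc needs >= 3 sequences")
    codes = _alignment_codes(aln)
    grid = settings.omega_grid()
    rng = np.random.default_rng(settings.seed)
    lik = _GridLikelihood(codes, grid, settings.n_orderings, rng)
    S = lik.n_sites

    mu, kappa = 0.1, 2.0
    table = lik.table(mu, kappa)
    omega_idx = np.full(S, int(np.argmin(np.abs(grid - 1.0))), dtype=np.int64)

    def total_ll(tab: np.ndarray) -> float:
        return float(tab[omega_idx, np.arange(S)].sum())

    ll = total_ll(table)
    log_grid = np.log(grid)
    kept_omega, kept_mu, kept_kappa = [], [], []
    acc_mu = acc_kappa = prop = 0
    step_mu, step_kappa = 0.25, 0.25

    for it in range(settings.iterations):
        prop += 1
        # mu (reuses the eigendecompositions of the current kappa)
        mu_new = mu * np.exp(step_mu * rng.standard_normal())
        tab_new = lik.table(mu_new, kappa)
        ll_new = float(tab_new[omega_idx, np.arange(S)].sum())
        log_alpha = (ll_new - ll
                     - settings.mu_prior_rate * (mu_new - mu)
                     + np.log(mu_new / mu))
        if np.log(rng.random()) < log_alpha:
            mu, table, ll = mu_new, tab_new, ll_new
            acc_mu += 1
        # kappa
        kappa_new = kappa * np.exp(step_kappa * rng.standard_normal())
        tab_new = lik.table(mu, kappa_new)
        ll_new = float(tab_new[omega_idx, np.arange(S)].sum())
        log_alpha = (ll_new - ll
                     - settings.kappa_prior_rate * (kappa_new - kappa)
                     + np.log(kappa_new / kappa))
        if np.log(rng.random()) < log_alpha:
            kappa, table, ll = kappa_new, tab_new, ll_new
            acc_kappa += 1
        # omega: exact Gibbs per site via the Gumbel-max trick
        gumbel = -np.log(-np.log(rng.random(table.shape)))
        omega_idx = np.argmax(table + gumbel, axis=0)
        ll = total_ll(table)
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            kept_omega.append(grid[omega_idx].copy())
            kept_mu.append(mu)
            kept_kappa.append(kappa)

    omega_samples = np.array(kept_omega)
    if len(omega_samples) < 10:
        warnings.warn("fewer than 10 retained samples; summaries are noisy")
    posteriors = summarise_samples(omega_samples, pbr_sites=pbr_sites)
    return OmegaRun(
        posteriors=posteriors, omega_samples=omega_samples,
        mu_samples=np.array(kept_mu), kappa_samples=np.array(kept_kappa),
        settings=settings,
        accept_mu=acc_mu / prop, accept_kappa=acc_kappa / prop,
    )


def summarise_samples(omega_samples: np.ndarray,
                      pbr_sites: list[int] | None = None,
                      mass: float = 0.95) -> list[SitePosterior]:
    """Posterior summaries per codon site from raw omega samples."""
    pbr = sorted(pbr_sites) if pbr_sites else []
    out = []
    for s in range(omega_samples.shape[1]):
        x = omega_samples[:, s]
        lo, hi = _hpd(x, mass)
        site = s + 1
        dist = min((abs(site - p) for p in pbr), default=-1)
        out.append(SitePosterior(
            codon_site=site,
            omega_mean=float(x.mean()),
            hpd_low=lo, hpd_high=hi,
            pp_positive=float((x > 1.0).mean()),
            is_pbr=site in pbr,
            pbr_distance=dist,
        ))
    return out


def classify_selected_sites(posteriors: list[SitePosterior],
                            significant: float = 0.95,
                            highly_significant: float = 0.99) -> dict[int, str]:
    """Strict-threshold site classes: none / significant / highly_significant."""
    out = {}
    for p in posteriors:
        if p.pp_positive > highly_significant:
            out[p.codon_site] = "highly_significant"
        elif p.pp_positive > significant:
            out[p.codon_site] = "significant"
        else:
            out[p.codon_site] = "none"
    return out


def compare_runs(run1: OmegaRun, run2: OmegaRun, tolerance: float = 0.1):
    """Per-site agreement between two runs differing only in seed."""
    s1, s2 = run1.settings, run2.settings
    for name in ("iterations", "burn_in", "thinning", "n_orderings",
                 "omega_grid_size", "omega_min", "omega_max"):
        if getattr(s1, name) != getattr(s2, name):
            raise ValueError(f"runs differ in setting {name!r}")
    rows = []
    ok = True
    for p1, p2 in zip(run1.posteriors, run2.posteriors):
        d_mean = abs(p1.omega_mean - p2.omega_mean)
        d_pp = abs(p1.pp_positive - p2.pp_positive)
        passed = d_pp <= tolerance and d_mean <= tolerance * max(
            1.0, p1.omega_mean, p2.omega_mean)
        ok = ok and passed
        rows.append({"codon_site": p1.codon_site, "d_omega_mean": d_mean,
                     "d_pp_positive": d_pp, "pass": passed})
    return ok, rows


@dataclass(frozen=True)
class ZTestResult:
    alternative: str           # "dN>dS" | "dN<dS"
    statistic: float
    p_value: float
    site_subset: str
    variance_method: str = "bootstrap"
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _per_pair_site_counts(aln: Alignment, sites: list[int]):
    """NG86 components per (sequence pair, subset codon column).

    Returns (SD, ND, S, N) arrays of shape (n_pairs, len(sites)); columns
    unusable for a pair (gap/ambiguity/stop in either codon) are zero in
    all four arrays.
    """
    seqs = [s.upper() for _, s in aln.records]
    n = len(seqs)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    SD = np.zeros((len(pairs), len(sites)))
    ND = np.zeros_like(SD)
    S = np.zeros_like(SD)
    N = np.zeros_like(SD)
    codons = {}
    for k, seq in enumerate(seqs):
        codons[k] = [seq[3 * (c - 1): 3 * c] for c in sites]
    for p, (i, j) in enumerate(pairs):
        ci, cj = codons[i], codons[j]
        for s in range(len(sites)):
            ca, cb = ci[s], cj[s]
            if not (_usable_codon(ca) and _usable_codon(cb)):
                continue
            sa, na = codon_sites(ca)
            sb, nb = codon_sites(cb)
            ds, dn = codon_pair_differences(ca, cb)
            SD[p, s], ND[p, s] = ds, dn
            S[p, s], N[p, s] = (sa + sb) / 2, (na + nb) / 2
    return SD, ND, S, N


def _mean_dn_minus_ds(SD, ND, S, N, col_counts: np.ndarray) -> np.ndarray:
    """mean(dN) - mean(dS) over pairs for each column-count vector.

    ``col_counts`` is (n_sites, n_reps); saturated or siteless pairs are
    dropped from the means (pairwise deletion + NaN-ignoring mean).
    """
    sd = SD @ col_counts
    nd = ND @ col_counts
    s_sites = S @ col_counts
    n_sites = N @ col_counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s_sites > 0, sd / s_sites, np.nan)
        pn = np.where(n_sites > 0, nd / n_sites, np.nan)
        ds = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(ps, 0.74999) / 3.0),
                      np.nan)
        dn = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(pn, 0.74999) / 3.0),
                      np.nan)
        out = np.nanmean(dn, axis=0) - np.nanmean(ds, axis=0)
    return out


def codon_z_test(aln: Alignment, site_subset: list[int] | None,
                 alternative: str = "dN>dS",
                 bootstrap_reps: int = 1000, seed: int = 0,
                 subset_label: str = "all") -> ZTestResult:
    """Codon-based Z-test of mean dN vs mean dS over all sequence pairs.

    The statistic is oriented so that positive values favour the stated
    alternative; its standard error comes from bootstrapping codon sites
    within the subset.  One-tailed normal p-value.
    """
    if alternative not in ("dN>dS", "dN<dS"):
        raise ValueError("alternative must be 'dN>dS' or 'dN<dS'")
    n_codons = aln.n_sites // 3
    sites = list(site_subset) if site_subset is not None else list(
        range(1, n_codons + 1))
    if not sites:
        raise ValueError("empty site subset")
    sign = 1.0 if alternative == "dN>dS" else -1.0
    SD, ND, S, N = _per_pair_site_counts(aln, sites)
    if not (S.sum() > 0 and N.sum() > 0):
        raise ValueError("subset yields no countable sites")

    k = len(sites)
    observed = sign * float(_mean_dn_minus_ds(SD, ND, S, N,
                                              np.ones((k, 1)))[0])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, k, size=(bootstrap_reps, k))
    col_counts = np.zeros((k, bootstrap_reps))
    for b in range(bootstrap_reps):
        col_counts[:, b] = np.bincount(draws[b], minlength=k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boot = sign * _mean_dn_minus_ds(SD, ND, S, N, col_counts)
    se = float(np.nanstd(boot, ddof=1))
    if se == 0.0 or np.isnan(se):
        z = 0.0 if observed == 0.0 else float(np.sign(observed) * np.inf)
    else:
        z = observed / se
    p = float(norm.sf(z))
    return ZTestResult(alternative=alternative, statistic=float(z), p_value=p,
                       site_subset=subset_label, bootstrap_reps=bootstrap_reps,
                       seed=seed)


def plot_site_posteriors(posteriors: list[SitePosterior], path: str,
                         significant: float = 0.95,
                         highly_significant: float = 0.99) -> None:
    """Two-panel summary plot: omega trace with HPD band, and PP(omega>1)
    with the significance thresholds marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sites = [p.codon_site for p in posteriors]
    means = [p.omega_mean for p in posteriors]
    los = [p.hpd_low for p in posteriors]
    his = [p.hpd_high for p in posteriors]
    pps = [p.pp_positive for p in posteriors]
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 6))
    ax1.fill_between(sites, los, his, color="0.8", label="95% HPD")
    ax1.plot(sites, means, color="k", lw=1)
    ax1.axhline(1.0, ls="--", color="0.4")
    ax1.set_ylabel("dN/dS")
    ax1.set_yscale("log")
    ax2.plot(sites, pps, color="k", lw=1)
    for p in posteriors:
        if p.pp_positive > highly_significant:
            ax2.plot(p.codon_site, p.pp_positive, "ks", ms=5)
        elif p.pp_positive > significant:
            ax2.plot(p.codon_site, p.pp_positive, "s", mfc="none", mec="k", ms=5)
    ax2.set_ylabel("PP(omega > 1)")
    ax2.set_xlabel("codon site")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
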