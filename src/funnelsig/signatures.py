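"""96-class single-base-substitution spectrum statistics.

Mutational spectra are probability vectors over the 96 canonical
trinucleotide substitution classes (pyrimidine-strand convention, COSMIC
lexicographic row order, e.g. ``A[C>A]A``).  This module provides:

* reconstruction of a spectrum from a signature catalog and exposures,
* cosine similarity and a sampling-error-aware *rescaled* similarity — the
  observed cosine divided by the maximal similarity expected given the finite
  mutation count (mean cosine against multinomial bootstrap resamples),
* residual spectra after subtracting all signatures but one, for asking
  whether the leftover mutations look like that signature,
* a baseline non-negative least-squares attribution, and
* mutational-opportunity adjustment of a catalog to a window's trinucleotide
  content.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SBS96_CLASSES",
    "TRINUCLEOTIDES",
    "Spectrum",
    "class_contexts",
    "reconstruct",
    "cosine",
    "max_expected_similarity",
    "rescaled_similarity",
    "residual_spectrum",
    "attribute_nnls",
    "opportunity_adjust",
    "validate_catalog",
]

_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"

#: The 96 classes in standard lexicographic COSMIC row order.
SBS96_CLASSES = sorted(
    f"{five}[{sub}]{three}"
    for sub in _SUBS
    for five in _BASES
    for three in _BASES
)

#: The 32 pyrimidine-centred trinucleotide contexts.
TRINUCLEOTIDES = sorted(
    f"{five}{mid}{three}"
    for mid in "CT"
    for five in _BASES
    for three in _BASES
)

_CLASS_INDEX = {c: i for i, c in enumerate(SBS96_CLASSES)}


def class_contexts() -> list[str]:
    """Trinucleotide context (5' + ref + 3') of each of the 96 classes, in order."""
    return [c[0] + c[2] + c[6] for c in SBS96_CLASSES]


@dataclass(frozen=True)
class Spectrum:
    """A 96-class mutation spectrum with its total count n.

    ``counts`` may be integer counts or nonnegative weights; ``n`` defaults to
    the rounded sum and is used by bootstrap-based statistics.
    """

    counts: np.ndarray
    n: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (96,):
            raise ValueError("a spectrum has exactly 96 entries")
        if np.any(c < 0):
            raise ValueError("spectrum entries must be nonnegative")
        object.__setattr__(self, "counts", c)
        if self.n is None:
            object.__setattr__(self, "n", int(round(c.sum())))

    @property
    def freq(self) -> np.ndarray:
        s = self.counts.sum()
        if s == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return self.counts / s

    @classmethod
    def from_classes(cls, classes, n: int | None = None) -> "Spectrum":
        counts = np.zeros(96)
        for z in classes:
            counts[_CLASS_INDEX[z]] += 1
        return cls(counts, n)


def validate_catalog(catalog: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Check a catalog: 96 rows in canonical order, columns summing to 1."""
    if list(catalog.index) != SBS96_CLASSES:
        try:
            catalog = catalog.loc[SBS96_CLASSES]
        except KeyError as e:
            raise ValueError("catalog rows must be the 96 canonical classes") from e
    sums = catalog.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(f"catalog columns must sum to 1: {dict(bad.round(4))}")
    if catalog.columns.duplicated().any():
        raise ValueError("duplicate signature names in catalog")
    return catalog


def _as_freq(v) -> np.ndarray:
    if isinstance(v, Spectrum):
        return v.freq
    v = np.asarray(v, dtype=float)
    s = v.sum()
    if s <= 0:
        raise ValueError("zero vector has no direction")
    return v / s


def reconstruct(catalog: pd.DataFrame, exposures: pd.Series | dict) -> np.ndarray:
    """Reconstructed spectrum sum_s P(z|s) P(s), normalized to frequencies."""
    exposures = pd.Series(exposures, dtype=float)
    unknown = exposures.index.difference(catalog.columns)
    if len(unknown):
        raise KeyError(f"unknown signature(s): {list(unknown)}")
    v = catalog[exposures.index].to_numpy() @ exposures.to_numpy()
    return _as_freq(v)


def cosine(a, b) -> float:
    """Cosine similarity of two spectra (scale-invariant, in [0, 1])."""
    a = np.asarray(a.counts if isinstance(a, Spectrum) else a, dtype=float)
    b = np.asarray(b.counts if isinstance(b, Spectrum) else b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(a @ b / (na * nb))


def max_expected_similarity(spectrum: Spectrum, n_boot: int = 1000, seed: int = 0) -> float:
    """Maximal cosine similarity expected under sampling error.

    Mean cosine between the observed spectrum and ``n_boot`` multinomial
    resamples of its own count n: an upper bound on the attainable
    goodness-of-fit for a sample of that size.
    """
    if spectrum.n < 1:
        raise ValueError("spectrum must contain at least one mutation")
    rng = np.random.default_rng(seed)
    p = spectrum.freq
    boots = rng.multinomial(spectrum.n, p, size=n_boot).astype(float)
    norms = np.linalg.norm(boots, axis=1)
    sims = boots @ p / (norms * np.linalg.norm(p))
    return float(sims.mean())


def rescaled_similarity(
    observed: Spectrum, reconstructed, n_boot: int = 1000, seed: int = 0
) -> float:
    """Observed cosine similarity divided by the maximal expected similarity.

    Values near 1 indicate a fit as good as sampling error allows; the ratio
    can slightly exceed 1 by chance.
    """
    return cosine(observed, _as_freq(reconstructed)) / max_expected_similarity(
        observed, n_boot=n_boot, seed=seed
    )


def residual_spectrum(
    observed: Spectrum,
    catalog: pd.DataFrame,
    exposures: pd.Series | dict,
    exclude: str,
    alternatives: list[str] | None = None,
    clip_negative: bool = True,
):
    """Observed spectrum minus the contribution of all signatures except one.

    Subtracts sum_{s != exclude} P(z|s) P(s) from the observed frequencies
    (exposures interpreted as proportions after normalization).  Negative
    entries are clipped to 0 (count reported) and the residual renormalized,
    so it is comparable by cosine to probability vectors.  Returns
    ``(residual, cosines)`` where ``cosines`` compares the residual to the
    excluded signature, each alternative, and the uniform spectrum.
    """
    exposures = pd.Series(exposures, dtype=float)
    if exclude not in exposures.index:
        raise KeyError(f"excluded signature {exclude!r} not among exposures")
    w = exposures / exposures.sum()
    others = w.drop(exclude)
    obs = observed.freq
    resid = obs - catalog[others.index].to_numpy() @ others.to_numpy()
    n_clipped = int((resid < -1e-12).sum())
    if clip_negative:
        resid = np.clip(resid, 0.0, None)
    if resid.sum() <= 1e-12:
        raise ValueError("residual spectrum is identically zero")
    resid = resid / resid.sum()
    comps = {exclude: catalog[exclude].to_numpy()}
    for alt in alternatives or []:
        comps[alt] = catalog[alt].to_numpy()
    comps["uniform"] = np.full(96, 1.0 / 96)
    cosines = pd.Series({name: cosine(resid, v) for name, v in comps.items()})
    cosines.attrs["n_clipped"] = n_clipped
    return resid, cosines


def attribute_nnls(observed: Spectrum, catalog: pd.DataFrame) -> pd.Series:
    """Baseline non-negative least-squares signature attribution.

    Minimizes || catalog @ e - observed_freq ||_2 subject to e >= 0 and
    reports exposures as counts (proportions scaled by n).  This is a plain
    reconstruction-error attribution without sparsity selection.
    """
    if catalog.shape[1] == 0:
        raise ValueError("catalog is empty")
    A = catalog.to_numpy()
    corr = np.abs(np.corrcoef(A.T))
    np.fill_diagonal(corr, 0.0)
    if catalog.shape[1] > 1 and corr.max() > 0.999:
        warnings.warn("near-duplicate catalog columns: attribution is degenerate")
    e, _ = optimize.nnls(A, observed.freq)
    s = e.sum()
    props = e / s if s > 0 else e
    return pd.Series(props * observed.n, index=catalog.columns, name="exposure")


def opportunity_adjust(
    catalog: pd.DataFrame,
    window_context: pd.Series | dict,
    genome_context: pd.Series | dict,
) -> pd.DataFrame:
    """Rescale a catalog to a window's trinucleotide (mutational-opportunity) content.

    Each class probability is multiplied by the window/genome ratio of its
    context frequency, then each signature is renormalized.  Adjusting by
    (w/g) and then (g/w) round-trips to the original catalog.
    """
    wc = pd.Series(window_context, dtype=float)
    gc = pd.Series(genome_context, dtype=float)
    ctx = class_contexts()
    missing = set(ctx) - set(wc.index) | set(ctx) - set(gc.index)
    if missing:
        raise KeyError(f"missing trinucleotide frequencies: {sorted(missing)[:4]}...")
    if (wc[ctx] <= 0).any() or (gc[ctx] <= 0).any():
        raise ValueError("all 32 context frequencies must be positive")
    ratio = (wc[ctx].to_numpy() / gc[ctx].to_numpy())[:, None]
    adj = catalog.to_numpy() * ratio
    adj = adj / adj.sum(axis=0, keepdims=True)
    return pd.DataFrame(adj, index=catalog.index, columns=catalog.columns)
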