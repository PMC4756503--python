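"""Cohort genotype simulation and haplotype-frequency estimation.

Genotypes are simulated locus by locus, independently across loci (linkage
equilibrium between loci, random mating within). A single-SNP locus draws
the risk-allele count from Binomial(2, q) — Hardy-Weinberg equilibrium at
allele frequency q. A multi-SNP locus draws two haplotypes independently
from a haplotype pool or frequency model, preserving within-locus LD.
Unphased input genotypes can be turned into a frequency model with the
standard expectation-maximisation estimator for multinomial haplotype
frequencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Locus

__all__ = [
    "HaplotypeModel",
    "CohortGenotypes",
    "em_haplotypes",
    "simulate_genotypes",
    "read_haplotype_fixture",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class HaplotypeModel:
    """Haplotype frequencies over the SNPs of one locus.

    ``haplotypes`` is an H x k matrix of 0/1 allele indicators (1 = risk
    allele) and ``frequencies`` the matching probability vector.
    """

    snp_ids: tuple[str, ...]
    haplotypes: np.ndarray
    frequencies: np.ndarray
    em_converged: bool = True

    def __post_init__(self) -> None:
        haps = np.asarray(self.haplotypes, dtype=np.int8)
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "haplotypes", haps)
        object.__setattr__(self, "frequencies", freqs)
        if haps.ndim != 2 or haps.shape[1] != len(self.snp_ids):
            raise ValueError("haplotype matrix shape does not match SNP list")
        if haps.shape[0] != freqs.shape[0]:
            raise ValueError("one frequency per haplotype required")
        if haps.shape[0] == 0:
            raise ValueError("haplotype model must contain at least one haplotype")
        if np.any(freqs < -_FREQ_TOL) or abs(freqs.sum() - 1.0) > 1e-6:
            raise ValueError("haplotype frequencies must be >= 0 and sum to 1")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def allele_freqs(self) -> np.ndarray:
        """Implied per-SNP risk-allele frequencies."""
        return self.frequencies @ self.haplotypes

    def pairwise_r2(self, i: int, j: int) -> float:
        """Implied r² between SNPs ``i`` and ``j`` of the locus."""
        pa = float(self.frequencies @ self.haplotypes[:, i])
        pb = float(self.frequencies @ self.haplotypes[:, j])
        pab = float(self.frequencies @ (self.haplotypes[:, i] * self.haplotypes[:, j]))
        denom = pa * (1 - pa) * pb * (1 - pb)
        if denom <= 0.0:
            return 0.0
        return (pab - pa * pb) ** 2 / denom

    def diplotype_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """All distinct genotype vectors and their probabilities.

        Diplotypes are unordered pairs of haplotypes drawn independently
        (random mating); genotype vectors sum the two haplotypes.
        """
        H = self.haplotypes.shape[0]
        probs: dict[tuple[int, ...], float] = {}
        for a in range(H):
            for b in range(H):
                p = float(self.frequencies[a] * self.frequencies[b])
                if p == 0.0:
                    continue
                g = tuple(int(x) for x in (self.haplotypes[a] + self.haplotypes[b]))
                probs[g] = probs.get(g, 0.0) + p
        genos = np.array(sorted(probs), dtype=np.int8)
        return genos, np.array([probs[tuple(g)] for g in genos])

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n individuals as two independent haplotypes each."""
        idx = rng.choice(len(self.frequencies), size=(n, 2), p=self.frequencies)
        return (self.haplotypes[idx[:, 0]] + self.haplotypes[idx[:, 1]]).astype(np.int8)

    @classmethod
    def from_phased_pool(
        cls, snp_ids: Sequence[str], haplotypes: np.ndarray, counts: Sequence[float]
    ) -> "HaplotypeModel":
        """Build a model from a pool of phased haplotypes with counts.

        Sampling from the resulting frequencies is the bootstrap-with-
        replacement over the pool.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.sum() <= 0:
            raise ValueError("phased pool is empty")
        return cls(
            snp_ids=tuple(snp_ids),
            haplotypes=np.asarray(haplotypes, dtype=np.int8),
            frequencies=counts / counts.sum(),
        )


@dataclass(frozen=True)
class CohortGenotypes:
    """n x k matrix of risk-allele counts with its SNP column order."""

    matrix: np.ndarray
    snp_ids: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != len(self.snp_ids):
            raise ValueError("genotype matrix shape does not match SNP list")
        if m.size and (m.min() < 0 or m.max() > 2):
            raise ValueError("genotype entries must be in {0, 1, 2}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Sub-matrix for the requested SNPs, in the requested order."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise KeyError(f"SNPs absent from genotype matrix: {missing}")
        return self.matrix[:, [index[s] for s in snp_ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.snp_ids))


def _enumerate_haplotypes(k: int) -> np.ndarray:
    return np.array(list(itertools.product((0, 1), repeat=k)), dtype=np.int8)


def em_haplotypes(
    genotypes: np.ndarray,
    snp_ids: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeModel:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Standard multinomial EM: the E-step distributes each individual's
    genotype over its compatible ordered haplotype pairs in proportion to
    current pair probabilities; the M-step sets each haplotype frequency to
    its expected share of the 2n sampled haplotypes. The log-likelihood is
    non-decreasing; iteration stops when it improves by less than ``tol``
    or after ``max_iter`` sweeps (then ``em_converged`` is False).

    Initial frequencies are the linkage-equilibrium products of the
    observed allele frequencies, with a small symmetric perturbation so a
    ridge of the likelihood does not trap the iteration.
    """
    G = np.asarray(genotypes, dtype=np.int8)
    if G.ndim != 2 or G.shape[0] < 1:
        raise ValueError("need a 2-D genotype matrix with at least one individual")
    if G.size and (G.min() < 0 or G.max() > 2):
        raise ValueError("genotype entries must be in {0, 1, 2}")
    n, k = G.shape
    if k > 16:
        raise ValueError("EM enumeration supports at most 16 SNPs per locus")
    snp_ids = tuple(snp_ids) if snp_ids is not None else tuple(f"snp{i}" for i in range(k))

    haps = _enumerate_haplotypes(k)
    H = haps.shape[0]

    # group identical genotype rows; compatible ordered pairs per pattern
    patterns, counts = np.unique(G, axis=0, return_counts=True)
    pair_a: list[np.ndarray] = []
    pair_b: list[np.ndarray] = []
    for g in patterns:
        het = np.flatnonzero(g == 1)
        fixed_half = (g // 2).astype(np.int8)
        a_list, b_list = [], []
        for bits in itertools.product((0, 1), repeat=len(het)):
            ha = fixed_half.copy()
            ha[het] = bits
            hb = (g - ha).astype(np.int8)
            a_list.append(int(ha @ (1 << np.arange(k - 1, -1, -1))) if k else 0)
            b_list.append(int(hb @ (1 << np.arange(k - 1, -1, -1))) if k else 0)
        pair_a.append(np.array(a_list, dtype=np.intp))
        pair_b.append(np.array(b_list, dtype=np.intp))

    q = G.mean(axis=0) / 2.0
    freqs = np.prod(np.where(haps == 1, q, 1.0 - q), axis=1)
    # symmetric jitter, renormalised; keeps strictly positive start
    freqs = freqs + 1e-6
    freqs /= freqs.sum()

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        new = np.zeros(H)
        ll = 0.0
        for idx in range(len(patterns)):
            a, b = pair_a[idx], pair_b[idx]
            w = freqs[a] * freqs[b]
            total = w.sum()
            if total <= 0.0:
                continue
            ll += counts[idx] * np.log(total)
            share = counts[idx] * w / total
            np.add.at(new, a, share)
            np.add.at(new, b, share)
        freqs = new / (2.0 * n)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    return HaplotypeModel(
        snp_ids=snp_ids, haplotypes=haps, frequencies=freqs, em_converged=converged
    )


def simulate_genotypes(
    loci: Sequence[Locus],
    n: int,
    seed: int | np.random.Generator | None = None,
    hap_models: Mapping[str, HaplotypeModel] | None = None,
) -> CohortGenotypes:
    """Simulate risk-allele counts for ``n`` individuals across loci.

    Single-SNP loci use Binomial(2, raf); multi-SNP loci require a
    :class:`HaplotypeModel` (attached via ``hap_models`` keyed by locus id)
    and draw two haplotypes per individual. Loci are mutually independent.
    The result is bit-reproducible given the same seed and inputs.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap_models = hap_models or {}
    blocks: list[np.ndarray] = []
    snp_ids: list[str] = []
    for locus in loci:
        if len(locus) == 1:
            snp = locus.snps[0]
            if not (0.0 < snp.raf < 1.0):
                raise ValueError(f"{snp.rsid}: allele frequency must be in (0, 1)")
            blocks.append(
                rng.binomial(2, snp.raf, size=(n, 1)).astype(np.int8)
            )
            snp_ids.append(snp.rsid)
        else:
            model = hap_models.get(locus.locus_id)
            if model is None:
                raise ValueError(
                    f"locus {locus.locus_id} has {len(locus)} SNPs but no haplotype model"
                )
            if tuple(model.snp_ids) != locus.rsids:
                raise ValueError(
                    f"haplotype model for locus {locus.locus_id} covers {model.snp_ids}, "
                    f"expected {locus.rsids}"
                )
            blocks.append(model.sample_genotypes(n, rng))
            snp_ids.extend(locus.rsids)
    matrix = np.hstack(blocks) if blocks else np.empty((n, 0), dtype=np.int8)
    seed_val = seed if isinstance(seed, int) else None
    return CohortGenotypes(matrix=matrix, snp_ids=tuple(snp_ids), seed=seed_val)


def read_haplotype_fixture(path: str | Path) -> dict[str, HaplotypeModel]:
    """Read a haplotype fixture TSV into per-locus models.

    Columns: ``locus_id``, ``haplotype`` (e.g. ``"010"``), and either
    ``frequency`` or ``count`` (phased-pool form). SNP ids default to
    positional names; callers binding models to catalog loci should rebuild
    with the correct ids via :meth:`HaplotypeModel.from_phased_pool`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "haplotype": str})
    weight_col = "frequency" if "frequency" in df.columns else "count"
    if weight_col not in df.columns:
        raise ValueError(f"{path}: need a 'frequency' or 'count' column")
    models: dict[str, HaplotypeModel] = {}
    for locus_id, grp in df.groupby("locus_id", sort=True):
        haps = np.array([[int(c) for c in h] for h in grp["haplotype"]], dtype=np.int8)
        weights = grp[weight_col].to_numpy(dtype=float)
        models[locus_id] = HaplotypeModel.from_phased_pool(
            snp_ids=[f"{locus_id}_snp{i}" for i in range(haps.shape[1])],
            haplotypes=haps,
            counts=weights,
        )
    return models
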