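"""Case-control GWAS simulation from penetrance models.

A penetrance model over k interacting biallelic SNPs assigns a disease
probability f(g) to each of the 3^k joint genotypes; genotypes follow
Hardy-Weinberg equilibrium at each SNP's minor-allele frequency (MAF), with
loci independent.  Derived quantities follow the usual definitions:

* prevalence   K  = sum_g P(g) f(g)
* heritability h2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K))
* marginal penetrance of SNP i at genotype a: M_i(a) = sum_{g: g_i = a} P(g | g_i = a) f(g)

A model has *no marginal effects* when every SNP's three marginal penetrances
are equal (to K).  ``find_dnme_model`` searches for such models at a requested
heritability by alternating an exact equal-marginals projection with an affine
rescale of the penetrance table (both preserve prevalence; the rescale scales
h2 quadratically), clipping into [0, 1] as needed.

``generate_dataset`` fills case and control quotas by rejection sampling
(draw functional genotypes from HWE, assign disease with probability f(g)),
surrounds the functional SNPs with independent HWE noise SNPs, and records the
planted interaction in a ground-truth manifest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Dataset, GroundTruth

__all__ = [
    "PenetranceModel",
    "genotype_freqs",
    "model_stats",
    "find_dnme_model",
    "generate_dataset",
    "read_penetrance_table",
    "write_penetrance_table",
    "ModelSearchError",
    "DegenerateModelError",
]


class ModelSearchError(RuntimeError):
    pass


class DegenerateModelError(ValueError):
    pass


def genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2) at MAF p."""
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


@dataclass
class PenetranceModel:
    """k interacting SNPs: per-SNP MAFs and a 3^k penetrance table."""

    mafs: tuple[float, ...]
    table: np.ndarray
    model_id: str = "model"

    def __post_init__(self):
        self.mafs = tuple(float(m) for m in self.mafs)
        self.table = np.asarray(self.table, dtype=np.float64).reshape((3,) * self.k)
        if (self.table < 0).any() or (self.table > 1).any():
            raise ValueError("penetrances must lie in [0, 1]")
        for m in self.mafs:
            genotype_freqs(m)  # validates range

    @property
    def k(self) -> int:
        return len(self.mafs)

    def genotype_probs(self) -> np.ndarray:
        """Joint HWE probability of every genotype combination; sums to 1."""
        probs = genotype_freqs(self.mafs[0])
        for m in self.mafs[1:]:
            probs = np.multiply.outer(probs, genotype_freqs(m))
        return probs


def model_stats(model: PenetranceModel) -> tuple[float, float, list[np.ndarray]]:
    """Prevalence K, heritability h2, and per-SNP marginal penetrance vectors."""
    probs = model.genotype_probs()
    f = model.table
    prevalence = float((probs * f).sum())
    if prevalence <= 0.0 or prevalence >= 1.0:
        raise DegenerateModelError(f"prevalence {prevalence} leaves h2 undefined")
    h2 = float((probs * (f - prevalence) ** 2).sum() / (prevalence * (1 - prevalence)))
    marginals = []
    for i in range(model.k):
        axes = tuple(a for a in range(model.k) if a != i)
        num = np.moveaxis(probs * f, i, 0).sum(axis=tuple(range(1, model.k)))
        marginals.append(num / genotype_freqs(model.mafs[i]))
    return prevalence, h2, marginals


def _project_equal_marginals(f: np.ndarray, freqs: list[np.ndarray]) -> np.ndarray:
    """Remove every SNP's marginal deviation from the table mean.

    One sweep suffices: subtracting a zero-mean per-genotype offset along one
    axis leaves both the prevalence and every other SNP's marginals unchanged.
    """
    k = f.ndim
    probs = freqs[0]
    for fr in freqs[1:]:
        probs = np.multiply.outer(probs, fr)
    prevalence = (probs * f).sum()
    out = f.copy()
    for i in range(k):
        marg = np.moveaxis(probs * out, i, 0).sum(axis=tuple(range(1, k))) / freqs[i]
        shape = [1] * k
        shape[i] = 3
        out = out - (marg - prevalence).reshape(shape)
    return out


def find_dnme_model(
    k: int,
    mafs,
    target_h2: float,
    tol: float = 1e-3,
    rng=None,
    max_tries: int = 10_000,
    model_id: str | None = None,
) -> PenetranceModel:
    """Search for a no-marginal-effect penetrance model at a target heritability.

    Starts from a random table and alternates (a) exact projection onto the
    equal-marginals affine subspace, (b) the affine rescale
    ``f <- K + c (f - K)`` with ``c = sqrt(target_h2 / h2)``, and (c) clipping
    to [0, 1], until both the marginal spread and ``|h2 - target_h2|`` are
    within ``tol``.
    """
    if not (0.0 < target_h2 < 1.0):
        raise ValueError("target_h2 must be in (0, 1)")
    rng = np.random.default_rng(rng)
    mafs = tuple(float(m) for m in mafs)
    if len(mafs) != k:
        raise ValueError("need one MAF per SNP")
    freqs = [genotype_freqs(m) for m in mafs]
    probs = freqs[0]
    for fr in freqs[1:]:
        probs = np.multiply.outer(probs, fr)

    for _ in range(max_tries):
        f = rng.uniform(0.05, 0.95, size=(3,) * k)
        for _ in range(200):
            f = _project_equal_marginals(f, freqs)
            f = np.clip(f, 0.0, 1.0)
            prevalence = (probs * f).sum()
            if prevalence <= 1e-6 or prevalence >= 1 - 1e-6:
                break
            var = (probs * (f - prevalence) ** 2).sum()
            h2 = var / (prevalence * (1 - prevalence))
            if h2 <= 1e-12:
                break
            f = prevalence + np.sqrt(target_h2 / h2) * (f - prevalence)
            clipped = (f < 0.0).any() or (f > 1.0).any()
            f = np.clip(f, 0.0, 1.0)
            if clipped:
                continue
            model = PenetranceModel(mafs=mafs, table=f, model_id=model_id or "dnme")
            prev, h2_now, margs = model_stats(model)
            spread = max(float(np.ptp(mg)) for mg in margs)
            if spread <= tol and abs(h2_now - target_h2) <= tol:
                if model_id is None:
                    model.model_id = f"dnme_k{k}_maf{mafs[0]:g}_h2{target_h2:g}"
                return model
    raise ModelSearchError(
        f"no model within tol={tol} of h2={target_h2} found in {max_tries} tries"
    )


def generate_dataset(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    n_snps: int,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    rng=None,
) -> tuple[Dataset, GroundTruth]:
    """Simulate a case-control dataset with the model's interaction planted.

    Functional genotypes are drawn from HWE and disease status from the
    penetrance table until both class quotas are filled (excess draws of a
    filled class are discarded).  Noise SNPs are independent HWE draws with
    per-SNP MAF uniform in ``noise_maf_range``.  Functional SNPs occupy
    uniformly chosen columns named ``M0P0..M0P{k-1}``; noise columns are
    named ``N{j}``.
    """
    rng = np.random.default_rng(rng)
    k = model.k
    if n_snps < k:
        raise ValueError("n_snps must be >= model order")
    prevalence, _, _ = model_stats(model)  # raises if degenerate

    flat = model.table.reshape(-1)
    freqs = [genotype_freqs(m) for m in model.mafs]
    need = {0: n_controls, 1: n_cases}
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    while need[0] > len(got[0]) or need[1] > len(got[1]):
        batch = 4096
        cols = [rng.choice(3, size=batch, p=fr) for fr in freqs]
        geno = np.stack(cols, axis=1)
        idx = geno @ (3 ** np.arange(k - 1, -1, -1))
        disease = rng.random(batch) < flat[idx]
        for row, is_case in zip(geno, disease):
            y = int(is_case)
            if len(got[y]) < need[y]:
                got[y].append(row)

    n_samples = n_cases + n_controls
    functional = np.vstack(got[0] + got[1]).astype(np.int8)
    phenotype = np.concatenate(
        [np.zeros(n_controls, dtype=np.int8), np.ones(n_cases, dtype=np.int8)]
    )

    noise_mafs = rng.uniform(noise_maf_range[0], noise_maf_range[1], size=n_snps - k)
    noise = np.empty((n_samples, n_snps - k), dtype=np.int8)
    for j, maf in enumerate(noise_mafs):
        noise[:, j] = rng.binomial(2, maf, size=n_samples)

    positions = np.sort(rng.choice(n_snps, size=k, replace=False))
    genotypes = np.empty((n_samples, n_snps), dtype=np.int8)
    names = [""] * n_snps
    noise_j = 0
    func_j = 0
    pos_set = set(int(p) for p in positions)
    for col in range(n_snps):
        if col in pos_set:
            genotypes[:, col] = functional[:, func_j]
            names[col] = f"M0P{func_j}"
            func_j += 1
        else:
            genotypes[:, col] = noise[:, noise_j]
            names[col] = f"N{noise_j}"
            noise_j += 1

    dataset = Dataset(genotypes=genotypes, phenotype=phenotype, snp_names=names)
    truth = GroundTruth(
        functional_sets=[frozenset(f"M0P{i}" for i in range(k))],
        model_id=model.model_id,
    )
    return dataset, truth


def write_penetrance_table(model: PenetranceModel, path: str | Path) -> None:
    """Write a model as headered TSV: a MAF line, then one row per genotype combo."""
    path = Path(path)
    lines = [f"#maf\t" + "\t".join(f"{m:g}" for m in model.mafs)]
    lines.append("\t".join([f"g{i}" for i in range(model.k)] + ["penetrance"]))
    for combo in itertools.product(range(3), repeat=model.k):
        lines.append(
            "\t".join([*(str(g) for g in combo), repr(float(model.table[combo]))])
        )
    path.write_text("\n".join(lines) + "\n")


def read_penetrance_table(path: str | Path, model_id: str | None = None) -> PenetranceModel:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#maf"):
        raise ValueError(f"{path}: expected a '#maf' line first")
    mafs = tuple(float(x) for x in lines[0].split("\t")[1:])
    k = len(mafs)
    table = np.zeros((3,) * k)
    for ln in lines[2:]:
        fields = ln.split("\t")
        combo = tuple(int(g) for g in fields[:k])
        table[combo] = float(fields[k])
    return PenetranceModel(mafs=mafs, table=table, model_id=model_id or path.stem)
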