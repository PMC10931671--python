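"""Synthetic label-free proteomics datasets with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a ~1400-protein x 16-sample (8 resilient + 8 susceptible) intensity
table on the 1e6-1e8 scale, with

* *differential* proteins carrying a multiplicative group effect,
* *class-separating* proteins whose class value supports are disjoint by a
  requested standardized margin,
* *pair-separable* feature pairs that overlap individually but whose sum
  separates the classes (the target the masked sequential selection stage
  exists to find), and
* completely-at-random missingness plus a low-peptide-evidence fraction to
  exercise the filter.

Planted-role proteins are kept fully observed and above the evidence
threshold so the planted structure is exactly recoverable; everything else
is noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import SpecError
from .io_quant import ProteinQuantTable

RESILIENT = "resilient"
SUSCEPTIBLE = "susceptible"
CONTROL = "control"


@dataclass
class SyntheticSpec:
    """All generator parameters; identical spec + seed => identical table.

    Defaults mirror the study conditions: 1400 proteins over 8+8 samples,
    log10 intensities centred at 7 (SD 0.6 across proteins), ~350
    differential and 45 class-separating proteins.
    """

    n_per_group: int = 8
    n_proteins: int = 1400
    n_de: int = 350
    de_log2fc_range: tuple[float, float] = (0.4, 2.0)
    n_classsep: int = 45
    classsep_margin: float = 1.0
    n_pairsep: int = 2
    missing_rate: float = 0.05
    base_log10_mean: float = 7.0
    base_log10_sd: float = 0.6
    within_log10_sd: float = 0.15
    low_evidence_rate: float = 0.05
    n_control: int = 0
    missing_mechanism: str = "mcar"  # or "mnar" (intensity-dependent)
    seed: int = 0

    def validate(self) -> None:
        if self.n_de + self.n_classsep + 2 * self.n_pairsep > self.n_proteins:
            raise SpecError(
                "role counts exceed n_proteins: "
                f"{self.n_de}+{self.n_classsep}+2*{self.n_pairsep} > {self.n_proteins}"
            )
        for name in ("missing_rate", "low_evidence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0,1], got {v}")
        if self.classsep_margin <= 0:
            raise SpecError("classsep_margin must be > 0")
        if self.n_per_group < 2:
            raise SpecError("n_per_group must be >= 2")
        if min(self.n_de, self.n_classsep, self.n_pairsep, self.n_control) < 0:
            raise SpecError("counts must be nonnegative")
        if self.missing_mechanism not in ("mcar", "mnar"):
            raise SpecError(f"unknown missing_mechanism {self.missing_mechanism!r}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["de_log2fc_range"] = list(self.de_log2fc_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "de_log2fc_range" in d:
            d["de_log2fc_range"] = tuple(d["de_log2fc_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Which planted role each protein plays, with effect sizes."""

    de_effects: dict[str, float] = field(default_factory=dict)     # id -> signed log2 FC (R/S)
    classsep: dict[str, tuple[str, float]] = field(default_factory=dict)  # id -> (high class, margin)
    pairsep_ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def de_ids(self) -> set[str]:
        return set(self.de_effects)

    @property
    def classsep_ids(self) -> set[str]:
        return set(self.classsep)


def assign_phenotype(sp_baseline: float, sp_week6: float) -> str:
    """Label an animal from its sucrose-preference trajectory.

    Susceptible iff the decrease in sucrose preference from baseline is
    >= 30% of baseline (anhedonia-like); resilient otherwise.  The boundary
    is inclusive.
    """
    for name, v in (("sp_baseline", sp_baseline), ("sp_week6", sp_week6)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be a preference percentage in [0,100], got {v}")
    if sp_baseline == 0:
        raise ValueError("decrease undefined: baseline sucrose preference is 0")
    decrease = (sp_baseline - sp_week6) / sp_baseline
    return SUSCEPTIBLE if decrease >= 0.30 else RESILIENT


def _standardized_gap(v: np.ndarray, high: np.ndarray, low: np.ndarray) -> float:
    sd = v.std()  # population SD, matching the preprocess convention
    if sd == 0:
        return 0.0
    return (high.min() - low.max()) / sd


def _plant_classsep(rng: np.random.Generator, n_low: int, n_high: int,
                    margin: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw (low, high) sample values whose standardized gap is >= margin."""
    low = rng.uniform(-1.5, -0.5, n_low)
    high = rng.uniform(0.5, 1.5, n_high)
    for _ in range(100):
        gap = _standardized_gap(np.concatenate([low, high]), high, low)
        if gap >= margin:
            break
        # widen the between-class shift; gap grows monotonically with it
        deficit = (margin - gap) * np.concatenate([low, high]).std() + 0.05
        high = high + deficit
    return low, high, _standardized_gap(np.concatenate([low, high]), high, low)


def _plant_pairsep(rng: np.random.Generator, n_low: int, n_high: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two features, individually overlapping, whose sum separates classes.

    Returns (f1, f2), each of length n_low + n_high with the low-class
    samples first.  The sum u = f1 + f2 has disjoint class supports with a
    standardized margin comfortably above 1 population SD.
    """
    u = np.concatenate([rng.uniform(-2.0, -1.2, n_low), rng.uniform(1.2, 2.0, n_high)])
    for _ in range(200):
        # marginal overlap: each member alone is informative but not separating
        w = rng.normal(0.0, 0.5, n_low + n_high)
        f1, f2 = u / 2 + w, u / 2 - w
        overlaps = all(
            f[:n_low].max() > f[n_low:].min() and f[n_low:].max() > f[:n_low].min()
            for f in (f1, f2)
        )
        if overlaps:
            return f1, f2
    raise SpecError("could not construct an individually-overlapping separable pair")


def _to_intensity(z: np.ndarray, log10_mu: float) -> np.ndarray:
    """Positive affine map of a score vector onto the LFQ intensity scale.

    Affine (not exponential) so that standardizing the stored intensities
    reproduces the planted standardized structure exactly.
    """
    shifted = z - z.min() + 0.5
    return shifted * (10.0 ** log10_mu / shifted.mean())


def generate_dataset(spec: SyntheticSpec) -> tuple[ProteinQuantTable, GroundTruth]:
    """Generate a ProteinQuantTable with known planted structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_r, n_s, n_c = spec.n_per_group, spec.n_per_group, spec.n_control
    samples = (
        [f"R{i+1}" for i in range(n_r)]
        + [f"S{i+1}" for i in range(n_s)]
        + [f"C{i+1}" for i in range(n_c)]
    )
    groups = dict(
        [(f"R{i+1}", RESILIENT) for i in range(n_r)]
        + [(f"S{i+1}", SUSCEPTIBLE) for i in range(n_s)]
        + [(f"C{i+1}", CONTROL) for i in range(n_c)]
    )
    r_idx = np.arange(0, n_r)
    s_idx = np.arange(n_r, n_r + n_s)
    p = spec.n_proteins
    width = len(str(p))
    ids = [f"SYN{i+1:0{width}d}" for i in range(p)]

    # baseline log-normal matrix
    mu = rng.normal(spec.base_log10_mean, spec.base_log10_sd, p)
    log10 = mu[:, None] + rng.normal(0.0, spec.within_log10_sd, (p, len(samples)))
    X = 10.0 ** log10

    # disjoint planted roles
    roles = rng.choice(p, size=spec.n_de + spec.n_classsep + 2 * spec.n_pairsep,
                       replace=False)
    de_rows = roles[: spec.n_de]
    cs_rows = roles[spec.n_de: spec.n_de + spec.n_classsep]
    pair_rows = roles[spec.n_de + spec.n_classsep:].reshape(spec.n_pairsep, 2)

    truth = GroundTruth()

    # differential proteins: multiplicative effect on the susceptible group,
    # so resilient-vs-control stays null; sign alternates (mixed directions)
    lo, hi = spec.de_log2fc_range
    for k, row in enumerate(de_rows):
        effect = rng.uniform(lo, hi)
        sign = 1.0 if k % 2 == 0 else -1.0
        # log2 FC on the resilient/susceptible orientation
        X[row, s_idx] *= 2.0 ** (-sign * effect)
        truth.de_effects[ids[row]] = sign * effect
        # a differential feature carries a mean shift, not disjoint supports:
        # pull the nearest boundary sample back into the other class's range
        r_vals, s_vals = X[row, r_idx], X[row, s_idx]
        if r_vals.min() > s_vals.max():
            X[row, r_idx[np.argmin(r_vals)]] = s_vals.max() * rng.uniform(0.90, 0.99)
        elif s_vals.min() > r_vals.max():
            X[row, s_idx[np.argmin(s_vals)]] = r_vals.max() * rng.uniform(0.90, 0.99)

    # class-separating proteins; direction alternates between classes
    for k, row in enumerate(cs_rows):
        high_class = RESILIENT if k % 2 == 0 else SUSCEPTIBLE
        z = np.empty(len(samples))
        if high_class == RESILIENT:
            low, high, margin = _plant_classsep(rng, n_s, n_r, spec.classsep_margin)
            z[s_idx], z[r_idx] = low, high
        else:
            low, high, margin = _plant_classsep(rng, n_r, n_s, spec.classsep_margin)
            z[r_idx], z[s_idx] = low, high
        if n_c:
            z[n_r + n_s:] = rng.uniform(-1.5, 1.5, n_c)
        X[row] = _to_intensity(z, mu[row])
        truth.classsep[ids[row]] = (high_class, float(margin))

    # pair-separable features
    for row1, row2 in pair_rows:
        f1, f2 = _plant_pairsep(rng, n_s, n_r)
        for row, f in ((row1, f1), (row2, f2)):
            z = np.empty(len(samples))
            z[s_idx], z[r_idx] = f[:n_s], f[n_s:]
            if n_c:
                z[n_r + n_s:] = rng.uniform(-1.0, 1.0, n_c)
            X[row] = _to_intensity(z, mu[row])
        truth.pairsep_ids.append((ids[row1], ids[row2]))

    role_rows = set(roles.tolist())

    # peptide evidence: >= 2 everywhere except a planted low-evidence fraction
    peptides = 2 + rng.poisson(5.0, p)
    unique = np.minimum(peptides, 2 + rng.poisson(2.0, p))
    noise_rows = np.array([i for i in range(p) if i not in role_rows])
    n_low = int(round(spec.low_evidence_rate * p))
    if n_low and len(noise_rows):
        low_rows = rng.choice(noise_rows, size=min(n_low, len(noise_rows)), replace=False)
        half = len(low_rows) // 2
        peptides[low_rows[:half]] = 1
        unique[low_rows[:half]] = 1
        unique[low_rows[half:]] = 1  # multi-peptide but single unique peptide

    intens = pd.DataFrame(X, index=pd.Index(ids, name="protein_id"), columns=samples)

    # missingness on noise features only (planted roles stay fully observed)
    if spec.missing_rate > 0 and len(noise_rows):
        if spec.missing_mechanism == "mcar":
            mask = rng.random((p, len(samples))) < spec.missing_rate
        else:  # intensity-dependent: low-abundance cells drop out first
            from scipy.stats import rankdata
            ranks = rankdata(X).reshape(X.shape) / X.size
            prob = spec.missing_rate * 2.0 * (1.0 - ranks)
            mask = rng.random((p, len(samples))) < prob
        mask[list(role_rows), :] = False
        group_cols = [r_idx, s_idx]
        if n_c:
            group_cols.append(np.arange(n_r + n_s, n_r + n_s + n_c))
        mask = _cap_missing_per_group(mask, group_cols, min_observed=2)
        vals = intens.to_numpy()
        vals[mask] = np.nan
        intens.iloc[:, :] = vals

    proteins = pd.DataFrame(
        {"gene": [f"Gene{i+1}" for i in range(p)],
         "peptides": peptides.astype(int),
         "unique_peptides": unique.astype(int)},
        index=intens.index,
    )
    table = ProteinQuantTable(proteins=proteins, intensities=intens, sample_group=groups)
    return table, truth


def _cap_missing_per_group(mask: np.ndarray, group_cols: list[np.ndarray],
                           min_observed: int) -> np.ndarray:
    """Unmask cells so each feature keeps >= min_observed values per group."""
    for cols in group_cols:
        sub = mask[:, cols]
        excess = sub.sum(axis=1) - (len(cols) - min_observed)
        for row in np.nonzero(excess > 0)[0]:
            masked_cols = cols[sub[row]]
            # deterministically unmask the first surplus cells
            mask[row, masked_cols[: excess[row]]] = False
    return mask


def null_spec(**overrides) -> SyntheticSpec:
    """A spec with no planted effects (for false-positive-rate checks)."""
    base = dict(n_de=0, n_classsep=0, n_pairsep=0, low_evidence_rate=0.0)
    base.update(overrides)
    return SyntheticSpec(**base)
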