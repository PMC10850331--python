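"""Synthetic two-protocol differentiation time-course RNA-seq simulator.

Emulates the design of a two-protocol (2D monolayer vs 3D aggregate) hiPSC
cardiac differentiation study: ten sampled days per protocol, three
replicates per condition (one condition run in duplicate), plus
undifferentiated seeding samples.  Stage-specific gene modules (pluripotency,
transient mesoderm, cardiac progenitor, cardiomyocyte, ...) are planted as
piecewise-linear log2 fold-change offsets over time, including an
endoderm-contaminant module that is only active in replicates with low
cardiomyocyte differentiation efficiency.  Counts are drawn from a negative
binomial with gene-wise dispersion, scaled to per-sample library sizes, and
the full ground truth is exported for downstream recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEED_PROTOCOL = "seed"
SEED_DAY = -1

# per-replicate cTNT+ fractions for the "paper" preset; chosen to span the
# roughly 45-90% range seen in replicate experiments, with 2D replicate 1
# the least and 3D replicate 2 the most efficient
PAPER_EFFICIENCY = {
    ("2D", 1): 0.45,
    ("2D", 2): 0.80,
    ("2D", 3): 0.55,
    ("3D", 1): 0.75,
    ("3D", 2): 0.90,
    ("3D", 3): 0.70,
}


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a two-protocol differentiation time-course experiment.

    Parameters
    ----------
    protocols:
        Differentiation protocol labels, e.g. ``("2D", "3D")``.
    days:
        Strictly increasing sampled time points (days of differentiation).
    replicates_per_condition:
        Replicate experiments per (protocol, day) condition.
    duplicated_conditions:
        Conditions sampled with one fewer replicate than the rest.
    n_seed_samples:
        Undifferentiated seeding samples collected before day 0.
    efficiency:
        Final differentiation efficiency (fraction in [0, 1]) per
        (protocol, replicate) experiment.
    """

    protocols: tuple[str, ...]
    days: tuple[int, ...]
    replicates_per_condition: int
    duplicated_conditions: tuple[tuple[str, int], ...] = ()
    n_seed_samples: int = 0
    efficiency: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        days = list(self.days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        for (proto, day) in self.duplicated_conditions:
            if proto not in self.protocols or day not in self.days:
                raise ValueError(f"unknown duplicated condition {(proto, day)}")
        for eff in self.efficiency.values():
            if not 0.0 <= eff <= 1.0:
                raise ValueError("efficiency values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        """Total sample count: |protocols|*|days|*replicates - duplicate deficits + seeds."""
        full = len(self.protocols) * len(self.days) * self.replicates_per_condition
        return full - len(self.duplicated_conditions) + self.n_seed_samples

    @property
    def n_conditions(self) -> int:
        """Distinct (protocol, day) conditions, plus one for the seed samples."""
        return len(self.protocols) * len(self.days) + (1 if self.n_seed_samples else 0)

    def sample_table(self) -> pd.DataFrame:
        """Per-sample metadata: sample_id, protocol, day, replicate, efficiency."""
        rows = []
        for rep in range(1, min(self.n_seed_samples, 10**6) + 1):
            rows.append((f"{SEED_PROTOCOL}_{rep}", SEED_PROTOCOL, SEED_DAY, rep, np.nan))
        for proto in self.protocols:
            for day in self.days:
                n_rep = self.replicates_per_condition
                if (proto, day) in self.duplicated_conditions:
                    n_rep -= 1
                for rep in range(1, n_rep + 1):
                    eff = self.efficiency.get((proto, rep), np.nan)
                    rows.append((f"{proto}_{day}_{rep}", proto, day, rep, eff))
        return pd.DataFrame(
            rows, columns=["sample_id", "protocol", "day", "replicate", "efficiency"]
        )


def make_design(preset: str | None = "paper", **custom) -> StudyDesign:
    """Build a :class:`StudyDesign`, either the built-in ``"paper"`` preset or custom.

    The ``"paper"`` preset mirrors the two-protocol cardiac differentiation
    study: 2 protocols x 10 days x 3 replicates, with (2D, day 12) performed
    in duplicate, plus 3 hiPSC seeding samples -- 62 samples in total.
    """
    if preset == "paper":
        if custom:
            raise ValueError("preset 'paper' takes no custom parameters")
        return StudyDesign(
            protocols=("2D", "3D"),
            days=(0, 1, 3, 5, 7, 9, 12, 15, 18, 20),
            replicates_per_condition=3,
            duplicated_conditions=(("2D", 12),),
            n_seed_samples=3,
            efficiency=dict(PAPER_EFFICIENCY),
        )
    if preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    custom.setdefault("duplicated_conditions", ())
    custom["protocols"] = tuple(custom["protocols"])
    custom["days"] = tuple(custom["days"])
    custom["duplicated_conditions"] = tuple(
        tuple(c) for c in custom["duplicated_conditions"]
    )
    return StudyDesign(**custom)


@dataclass
class GeneModule:
    """A planted co-expression module with a temporal log2FC effect profile.

    ``profile`` maps protocol -> list of (day, offset) breakpoints; offsets
    between breakpoints are linearly interpolated and held constant outside
    the breakpoint range.  ``seed_offset`` applies to seeding samples.
    ``max_efficiency`` gates the module: when set, the module is active only
    in replicates whose efficiency is strictly below the cut.
    """

    name: str
    member_genes: list[str]
    profile: dict[str, list[tuple[float, float]]]
    seed_offset: float = 0.0
    max_efficiency: float | None = None

    def offset(self, protocol: str, day: float, efficiency: float = np.nan) -> float:
        """Log2FC offset this module contributes to a sample."""
        if self.max_efficiency is not None:
            if not np.isfinite(efficiency) or efficiency >= self.max_efficiency:
                return 0.0
        if protocol == SEED_PROTOCOL:
            return self.seed_offset
        bp = self.profile.get(protocol)
        if bp is None:
            return 0.0
        xs = np.array([b[0] for b in bp], dtype=float)
        ys = np.array([b[1] for b in bp], dtype=float)
        return float(np.interp(day, xs, ys))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "member_genes": list(self.member_genes),
            "profile": {p: [[float(d), float(o)] for d, o in bp] for p, bp in self.profile.items()},
            "seed_offset": self.seed_offset,
            "max_efficiency": self.max_efficiency,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModule":
        return cls(
            name=d["name"],
            member_genes=list(d["member_genes"]),
            profile={p: [tuple(b) for b in bp] for p, bp in d["profile"].items()},
            seed_offset=d.get("seed_offset", 0.0),
            max_efficiency=d.get("max_efficiency"),
        )


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:03d}" for i in range(1, n + 1)]


def default_modules(
    n_genes_per_module: int = 50,
    contaminant_size: int = 10,
    contaminant_peak: float = 7.0,
    efficiency_cut: float = 0.6,
    pluripotency_decay: float = 5.0,
) -> list[GeneModule]:
    """Stage-specific gene modules of a two-protocol cardiac differentiation.

    Returns modules for the canonical differentiation stages: pluripotency
    (high in seeding samples and early days, then decaying), transient
    mesoderm in a rapidly-decaying (TBXT-like) and a sustained (ROR2-like)
    flavour, cardiac progenitor (rising from day 7), cardiomyocyte (rising
    from day 9), a translation/ribosome-like module expressed in seeding
    samples and 2D day 0 but silent in the 3D protocol, a 3D-only late
    maturation module, and an endoderm-contaminant module active from day 7
    onward only in replicates with efficiency below ``efficiency_cut``,
    peaking at ``contaminant_peak`` log2FC on day 9.
    """
    if n_genes_per_module < 1 or contaminant_size < 1:
        raise ValueError("module sizes must be >= 1")
    n = n_genes_per_module
    half_decay = pluripotency_decay / 2.0
    pluri = [(0, half_decay), (1, half_decay * 0.8), (3, 0.0), (5, -half_decay * 0.6),
             (7, -half_decay), (20, -half_decay)]
    meso_fast = [(0, 0.5), (1, 1.5), (3, 3.0), (5, 0.0), (7, -1.0), (20, -1.0)]
    meso_sustained = [(0, -1.0), (1, -1.0), (3, 3.0), (5, 3.0), (9, 3.0), (12, 2.0), (20, 2.0)]
    progenitor = [(0, -1.0), (5, -1.0), (7, 2.0), (9, 3.0), (20, 3.0)]
    cardiomyocyte = [(0, -1.5), (7, -1.5), (9, 1.5), (12, 3.0), (20, 3.5)]
    translation_2d = [(0, 2.0), (1, 1.0), (3, 0.0), (20, 0.0)]
    flat = [(0, 0.0), (20, 0.0)]
    maturation_3d = [(0, -1.0), (12, -1.0), (15, 2.0), (20, 3.0)]
    contaminant = [(0, 0.0), (5, 0.0), (7, contaminant_peak / 2.0),
                   (9, contaminant_peak), (20, contaminant_peak * 0.9)]
    both = lambda bp: {"2D": bp, "3D": bp}  # noqa: E731
    return [
        GeneModule("pluripotency", _gene_ids("PLURI", n), both(pluri),
                   seed_offset=half_decay),
        GeneModule("mesoderm_transient", _gene_ids("MESOT", n), both(meso_fast),
                   seed_offset=0.5),
        GeneModule("mesoderm_sustained", _gene_ids("MESOS", n), both(meso_sustained),
                   seed_offset=-1.0),
        GeneModule("cardiac_progenitor", _gene_ids("CPROG", n), both(progenitor),
                   seed_offset=-1.0),
        GeneModule("cardiomyocyte", _gene_ids("CMYO", n), both(cardiomyocyte),
                   seed_offset=-1.5),
        GeneModule("translation_ribosome", _gene_ids("RIBO", n),
                   {"2D": translation_2d, "3D": flat}, seed_offset=2.0),
        GeneModule("maturation_3d", _gene_ids("MAT3D", n),
                   {"2D": flat, "3D": maturation_3d}, seed_offset=0.0),
        GeneModule("endoderm_contaminant", _gene_ids("ENDO", contaminant_size),
                   both(contaminant), seed_offset=0.0, max_efficiency=efficiency_cut),
    ]


@dataclass
class SimulationTruth:
    """Everything needed to regenerate a synthetic dataset and score recovery."""

    design: StudyDesign
    modules: list[GeneModule]
    gene_ids: list[str]
    baseline_log_means: np.ndarray
    dispersions: np.ndarray
    library_sizes: np.ndarray
    seed: int

    def module_of(self) -> pd.Series:
        """Gene -> module name ('' for background genes)."""
        out = pd.Series("", index=pd.Index(self.gene_ids, name="gene_id"))
        for m in self.modules:
            out.loc[m.member_genes] = m.name
        return out

    def to_json(self, path: str | Path) -> None:
        d = self.design
        obj = {
            "design": {
                "protocols": list(d.protocols),
                "days": list(d.days),
                "replicates_per_condition": d.replicates_per_condition,
                "duplicated_conditions": [list(c) for c in d.duplicated_conditions],
                "n_seed_samples": d.n_seed_samples,
                "efficiency": [[p, r, e] for (p, r), e in sorted(d.efficiency.items())],
            },
            "modules": [m.to_dict() for m in self.modules],
            "gene_ids": self.gene_ids,
            "baseline_log_means": self.baseline_log_means.tolist(),
            "dispersions": self.dispersions.tolist(),
            "library_sizes": self.library_sizes.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        obj = json.loads(Path(path).read_text())
        d = obj["design"]
        design = StudyDesign(
            protocols=tuple(d["protocols"]),
            days=tuple(d["days"]),
            replicates_per_condition=d["replicates_per_condition"],
            duplicated_conditions=tuple(tuple(c) for c in d["duplicated_conditions"]),
            n_seed_samples=d["n_seed_samples"],
            efficiency={(p, r): e for p, r, e in d["efficiency"]},
        )
        return cls(
            design=design,
            modules=[GeneModule.from_dict(m) for m in obj["modules"]],
            gene_ids=list(obj["gene_ids"]),
            baseline_log_means=np.asarray(obj["baseline_log_means"], dtype=float),
            dispersions=np.asarray(obj["dispersions"], dtype=float),
            library_sizes=np.asarray(obj["library_sizes"], dtype=int),
            seed=obj["seed"],
        )


def make_truth(
    design: StudyDesign,
    modules: list[GeneModule] | None = None,
    n_genes: int = 5000,
    seed: int = 0,
    mean_library_size: float = 1e7,
    library_size_sigma: float = 0.3,
    dispersion_range: tuple[float, float] = (0.01, 0.5),
) -> SimulationTruth:
    """Draw gene-level and sample-level nuisance parameters for a simulation.

    Background genes fill the universe up to ``n_genes``; baseline (natural)
    log abundances are normal with unit-ish spread, dispersions log-uniform
    over ``dispersion_range``, library sizes log-normal around
    ``mean_library_size``.
    """
    if modules is None:
        modules = default_modules()
    module_genes = [g for m in modules for g in m.member_genes]
    if len(set(module_genes)) != len(module_genes):
        raise ValueError("module member genes must be disjoint across modules")
    n_bg = n_genes - len(module_genes)
    if n_bg < 0:
        raise ValueError("n_genes smaller than total module membership")
    gene_ids = module_genes + [f"BG_{i:05d}" for i in range(1, n_bg + 1)]
    rng = np.random.default_rng(seed)
    baseline = rng.normal(loc=3.0, scale=1.2, size=n_genes)
    lo, hi = dispersion_range
    if lo <= 0 or hi <= 0:
        raise ValueError("dispersions must be positive")
    disp = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    n_samples = design.n_samples
    libs = np.rint(
        mean_library_size * np.exp(rng.normal(0.0, library_size_sigma, size=n_samples))
    ).astype(int)
    return SimulationTruth(
        design=design,
        modules=modules,
        gene_ids=gene_ids,
        baseline_log_means=baseline,
        dispersions=disp,
        library_sizes=libs,
        seed=seed,
    )


def expected_offsets(truth: SimulationTruth) -> pd.DataFrame:
    """Planted gene x sample log2FC offset matrix (the noiseless signal)."""
    meta = truth.design.sample_table()
    out = pd.DataFrame(
        0.0, index=pd.Index(truth.gene_ids, name="gene_id"), columns=meta["sample_id"]
    )
    for m in truth.modules:
        for _, s in meta.iterrows():
            off = m.offset(s["protocol"], s["day"], s["efficiency"])
            if off:
                out.loc[m.member_genes, s["sample_id"]] += off
    return out


def simulate_counts(truth: SimulationTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a counts matrix (genes x samples) and its sample metadata.

    Per-gene relative means are ``exp(baseline + ln(2) * sum of active module
    offsets)``; each sample's means are rescaled so the expected column total
    equals its library size, then counts are drawn negative-binomial with the
    gene-wise dispersion (Poisson when dispersion underflows).  Deterministic
    for a fixed truth (seed included).
    """
    if np.any(truth.dispersions <= 0):
        raise ValueError("dispersions must be positive")
    if np.any(truth.library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    meta = truth.design.sample_table()
    if len(meta) != len(truth.library_sizes):
        raise ValueError("library_sizes length does not match the design")
    offsets = expected_offsets(truth).to_numpy()
    log_mu = truth.baseline_log_means[:, None] + np.log(2.0) * offsets
    mu = np.exp(log_mu)
    mu = mu / mu.sum(axis=0, keepdims=True) * truth.library_sizes[None, :]
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 941]))
    counts = _nb_draw(rng, mu, truth.dispersions[:, None])
    counts_df = pd.DataFrame(
        counts, index=pd.Index(truth.gene_ids, name="gene_id"),
        columns=meta["sample_id"].to_numpy(),
    )
    return counts_df, meta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + phi*mu^2."""
    phi = np.broadcast_to(phi, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = phi < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    if big.any():
        r = 1.0 / phi[big]
        p = r / (r + mu[big])
        out[big] = rng.negative_binomial(r, p)
    return out


def write_dataset(
    outdir: str | Path,
    truth: SimulationTruth,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
) -> None:
    """Write counts TSV, metadata TSV and ground-truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
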