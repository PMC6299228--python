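"""Quantitative physiology of reductive debromination.

Covers the arithmetic behind culture-based characterization of
organohalide-respiring bacteria: the bromine/electron ledger of bromophenol
debromination (two electrons consumed per bromine removed), protein yield
per mmol of electrons, phenol-ring mass balance over a time course, and
qPCR quantification by the relative standard-curve method with target
quantities normalized to the 16S rRNA gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: bromine substituent counts of the compounds handled by the ledger
BROMINE_COUNTS: dict[str, int] = {
    "2,6-DBP": 2,
    "2,4,6-TBP": 3,
    "2-BP": 1,
    "2,4-DBP": 2,
    "4-BP": 1,
    "phenol": 0,
}

ELECTRONS_PER_BROMINE = 2


def _bromines(compound: str) -> int:
    try:
        return BROMINE_COUNTS[compound]
    except KeyError:
        raise ValueError(
            f"unknown compound {compound!r}; known: "
            f"{sorted(BROMINE_COUNTS)}"
        ) from None


@dataclass
class DehalTimeSeries:
    """Concentration time course (µM) of a parent bromophenol and products."""

    times: np.ndarray  # hours
    species: dict[str, np.ndarray]  # name -> µM series
    volume_l: float = 0.1
    parent: str = "2,6-DBP"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.species = {k: np.asarray(v, dtype=float)
                        for k, v in self.species.items()}
        for name, series in self.species.items():
            if series.shape != self.times.shape:
                raise ValueError(f"series {name!r} length mismatch")
            if (series < -1e-9).any():
                raise ValueError(f"negative concentrations in {name!r}")
        if self.parent not in BROMINE_COUNTS:
            _bromines(self.parent)


def electron_equivalents(
    endpoint: dict[str, float], parent: str, volume_l: float
) -> float:
    """mmol of electrons consumed to form the observed products.

    Each product molecule accounts for (bromines(parent) - bromines(product))
    bromines removed, at two electrons per bromine:
    e- (mmol) = 2 x sum_products(Br_removed x conc_µM x V_L) / 1000.
    """
    nb_parent = _bromines(parent)
    total_umol = 0.0
    for compound, conc in endpoint.items():
        nb = _bromines(compound)
        if nb > nb_parent:
            raise ValueError(
                f"product {compound!r} has more bromines ({nb}) than "
                f"parent {parent!r} ({nb_parent})"
            )
        removed = nb_parent - nb
        total_umol += removed * conc * volume_l
    return ELECTRONS_PER_BROMINE * total_umol / 1000.0


def protein_yield(
    protein_mg: float | list[float], electrons_mmol: float
) -> tuple[float, float]:
    """Protein yield in mg per mmol electrons: (mean, sd over replicates).

    Scalar input returns sd 0. Sample standard deviation (ddof=1) across
    biological replicates.
    """
    if electrons_mmol <= 0:
        raise ValueError("electrons_mmol must be > 0")
    vals = np.atleast_1d(np.asarray(protein_mg, dtype=float)) / electrons_mmol
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


def mass_balance(
    ts: DehalTimeSeries, tolerance: float = 0.15
) -> tuple[np.ndarray, bool]:
    """Phenol-ring conservation check against the time-zero total.

    The molar sum over all ring species should stay constant as bromines are
    stripped; deviation_t = |sum_t - sum_0| / sum_0. Passes iff every
    deviation is <= tolerance (default 0.15, reflecting HPLC variability).
    """
    total = np.sum([ts.species[name] for name in ts.species], axis=0)
    if total[0] <= 0:
        raise ValueError("time-zero total concentration is zero")
    dev = np.abs(total - total[0]) / total[0]
    return dev, bool(np.all(dev <= tolerance + 1e-15))


# ---------------------------------------------------------------------------
# qPCR — relative standard curve method


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def quantity(self, cq: float | np.ndarray) -> float | np.ndarray:
        """Relative quantity interpolated from the curve: 10^((Cq-b)/m)."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept)
                        / self.slope)


@dataclass
class QpcrRun:
    """Standard-curve points and sample Cq values for one experiment.

    ``standards``: gene -> list of (log10 relative quantity, Cq).
    ``samples``: records with keys gene, condition ('induced'|'control'),
    bio_rep, tech_rep, cq — biological by technical replicate structure.
    """

    standards: dict[str, list[tuple[float, float]]]
    samples: list[dict] = field(default_factory=list)

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples)


def fit_standard_curve(
    standards: list[tuple[float, float]]
) -> StandardCurve:
    """Least-squares Cq = slope*log10(q) + intercept.

    Amplification efficiency is 10^(-1/slope) - 1 (1.0 == perfect
    doubling, slope -3.3219).
    """
    logq = np.array([s[0] for s in standards], dtype=float)
    cq = np.array([s[1] for s in standards], dtype=float)
    if len(set(logq.tolist())) < 2:
        raise ValueError("need >=2 distinct standard quantities")
    if (cq <= 0).any():
        raise ValueError("Cq values must be positive")
    fit = stats.linregress(logq, cq)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue ** 2), float(efficiency))


def relative_expression(
    run: QpcrRun,
    target_gene: str,
    reference_gene: str = "16S",
    induced: str = "induced",
    control: str = "control",
) -> tuple[float, float]:
    """Fold change of target expression, normalized to the reference gene.

    Per biological replicate, technical-replicate Cqs are averaged on the Cq
    scale, interpolated on the gene's standard curve, and the target
    quantity divided by the reference quantity. The fold change is
    mean(induced normalized) / mean(control normalized); the sd is across
    biological replicates of the per-replicate induced fold.
    """
    curves = {g: fit_standard_curve(pts) for g, pts in run.standards.items()}
    for gene in (target_gene, reference_gene):
        if gene not in curves:
            raise ValueError(f"no standard curve for gene {gene!r}")
    df = run.sample_frame()

    def normalized(condition: str) -> np.ndarray:
        sub = df[df["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no samples for condition {condition!r}")
        out = []
        for bio, grp in sub.groupby("bio_rep"):
            qty = {}
            for gene in (target_gene, reference_gene):
                cqs = grp[grp["gene"] == gene]["cq"]
                if cqs.empty:
                    raise ValueError(
                        f"missing {gene!r} Cq for {condition}/{bio}"
                    )
                qty[gene] = curves[gene].quantity(float(cqs.mean()))
            out.append(qty[target_gene] / qty[reference_gene])
        return np.array(out)

    norm_ind = normalized(induced)
    norm_ctl = normalized(control)
    ctl_mean = float(np.mean(norm_ctl))
    if ctl_mean <= 0:
        raise ValueError("control normalized quantity is zero")
    folds = norm_ind / ctl_mean
    sd = float(np.std(folds, ddof=1)) if folds.size > 1 else 0.0
    return float(np.mean(folds)), sd
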