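"""Retrospective-likelihood score test of deletion-carrier status against
breast or ovarian cancer risk in an ascertained BRCA1-carrier cohort.

Because carriers were sampled conditional on disease status (case-enriched),
a prospective survival likelihood would be biased; instead each sample
contributes the retrospective likelihood ``P(z_i | delta_i, t_i)`` of its
carrier genotype given its phenotype.  Under a proportional-hazards model
``lambda(t | z) = lambda0(t) * exp(beta * z)`` with known piecewise-constant
baseline hazard and carrier probability ``p``,

    P(delta=1, t | z) ∝ lambda0(t) e^{beta z} exp(-Lambda0(t) e^{beta z})
    P(delta=0, t | z) =  exp(-Lambda0(t) e^{beta z})

The 1-d.f. score test of ``H0: beta = 0`` with the plug-in null MLE
``p_hat = mean(z)`` has

    U = sum_i (z_i - p_hat) (delta_i - Lambda0(t_i))
    V = p_hat (1 - p_hat) * sum_i (delta_i - Lambda0(t_i))^2

and ``U^2 / V ~ chi^2_1``.  The one-step estimate ``beta_hat = U / V`` with
standard error ``1 / sqrt(V)`` yields the approximate relative risk
``RR = exp(beta_hat)`` and its 95% CI — the "score test" RR approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .incidence import IncidenceModel

__all__ = [
    "build_outcomes",
    "DeletionRiskModel",
    "DeletionRiskResults",
    "GenomewideResults",
    "run_genomewide",
    "discrete_fdr",
]

_EVENT_COLUMNS = ("age_bc_dx", "age_oc_dx", "age_mastectomy", "age_oophorectomy")


def _get(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def build_outcomes(phenotypes: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Censoring/classification rules per endpoint -> (sample, t, delta).

    Breast: analysis age is the first of breast cancer diagnosis, ovarian
    cancer diagnosis, bilateral prophylactic mastectomy, or last observation;
    affected only if that first event is the breast cancer diagnosis (samples
    censored at ovarian diagnosis count as unaffected).  Ovarian: first of
    ovarian diagnosis, bilateral prophylactic oophorectomy, or last
    observation, additionally bounded by the breast cancer diagnosis age
    (breast cases are treated as unaffected at their diagnosis age); affected
    only for the ovarian diagnosis.  Diagnosis wins age ties.
    """
    if endpoint not in ("breast", "ovarian"):
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    records = []
    for _, row in phenotypes.iterrows():
        last = _get(row, "age_last_obs")
        if last is None:
            raise ValidationError(f"sample {row['sample']!r}: age_last_obs missing")
        ages = {c: _get(row, c) for c in _EVENT_COLUMNS}
        for c, v in ages.items():
            if v is not None and v <= 0:
                raise ValidationError(f"sample {row['sample']!r}: {c} must be > 0")
            if v is not None and v > last:
                raise ValidationError(
                    f"sample {row['sample']!r}: {c}={v} after last observation {last}"
                )
        if last <= 0:
            raise ValidationError(f"sample {row['sample']!r}: age_last_obs must be > 0")
        if endpoint == "breast":
            candidates = [ages["age_bc_dx"], ages["age_oc_dx"], ages["age_mastectomy"], last]
            dx = ages["age_bc_dx"]
        else:
            candidates = [ages["age_oc_dx"], ages["age_oophorectomy"], ages["age_bc_dx"], last]
            dx = ages["age_oc_dx"]
        t = min(v for v in candidates if v is not None)
        delta = int(dx is not None and dx == t)
        records.append((str(row["sample"]), t, delta))
    return pd.DataFrame(records, columns=["sample", "t", "delta"])


@dataclass
class DeletionRiskResults:
    """Score-test results for one gene locus."""

    gene: str
    n: int
    carriers: int
    U: float
    V: float
    model: "DeletionRiskModel" = field(repr=False, default=None)

    @property
    def degenerate(self) -> bool:
        return self.V <= 0

    @property
    def chisq(self) -> float:
        return 0.0 if self.degenerate else self.U**2 / self.V

    @property
    def pvalue(self) -> float:
        return 1.0 if self.degenerate else float(stats.chi2.sf(self.chisq, df=1))

    @property
    def beta_hat(self) -> float:
        return np.nan if self.degenerate else self.U / self.V

    @property
    def rr(self) -> float:
        return np.nan if self.degenerate else float(np.exp(self.beta_hat))

    @property
    def rr_ci95(self):
        if self.degenerate:
            return (np.nan, np.nan)
        half = 1.96 / np.sqrt(self.V)
        return (float(np.exp(self.beta_hat - half)), float(np.exp(self.beta_hat + half)))

    @property
    def carrier_freq(self) -> float:
        return self.carriers / self.n

    def summary(self) -> str:
        lo, hi = self.rr_ci95
        lines = [
            "Retrospective-likelihood score test (1 d.f.)",
            f"  gene:            {self.gene}",
            f"  samples:         {self.n}  (carriers: {self.carriers}, "
            f"freq {100 * self.carrier_freq:.2f}%)",
            f"  score U:         {self.U:.4g}",
            f"  variance V:      {self.V:.4g}",
            f"  chi-square:      {self.chisq:.4g}",
            f"  P-value:         {self.pvalue:.4g}",
        ]
        if self.degenerate:
            lines.append("  RR:              undefined (degenerate: V = 0)")
        else:
            lines.append(f"  approx. RR:      {self.rr:.2f} (95% CI {lo:.2f}–{hi:.2f})")
        return "\n".join(lines)


class DeletionRiskModel:
    """Proportional-hazards modifier model fitted by retrospective likelihood.

    Parameters
    ----------
    t, delta
        Analysis age and affected indicator per sample (see
        :func:`build_outcomes`).
    z
        Binary deletion-carrier status per sample (dominant coding).
    incidence
        Known piecewise-constant baseline hazard for the endpoint.
    gene
        Label carried into the results.
    """

    def __init__(self, t, delta, z, incidence: IncidenceModel, gene: str = ""):
        self.t = np.asarray(t, dtype=float)
        self.delta = np.asarray(delta, dtype=float)
        self.z = np.asarray(z, dtype=float)
        if not (self.t.size == self.delta.size == self.z.size):
            raise ValidationError("t, delta and z must have equal length")
        if self.t.size < 2:
            raise ValidationError("need at least 2 samples")
        if np.any((self.z != 0) & (self.z != 1)) or np.any((self.delta != 0) & (self.delta != 1)):
            raise ValidationError("z and delta must be binary")
        self.incidence = incidence
        self.gene = gene
        self.cumhaz = incidence.cumulative_hazard(self.t)

    @classmethod
    def from_dataframe(cls, outcomes: pd.DataFrame, z: pd.Series,
                       incidence: IncidenceModel, gene: str = "") -> "DeletionRiskModel":
        """Build from an outcomes frame and a sample-indexed carrier series."""
        z_aligned = z.reindex(outcomes["sample"])
        if z_aligned.isna().any():
            missing = sorted(z_aligned.index[z_aligned.isna()])
            raise ValidationError(f"carrier status missing for samples: {missing[:10]}")
        return cls(outcomes["t"], outcomes["delta"], z_aligned.to_numpy(), incidence, gene)

    @property
    def nobs(self) -> int:
        return self.t.size

    def loglike(self, beta: float, p: float | None = None) -> float:
        """Retrospective log-likelihood sum_i log P(z_i | delta_i, t_i).

        Terms independent of z (the ``delta * log lambda0(t)`` factor) cancel
        between numerator and normalizer and are omitted.
        """
        if p is None:
            p = float(np.mean(self.z))
        lam = self.cumhaz
        g1 = self.delta * beta - lam * np.exp(beta)  # log P(obs | z=1) + const
        g0 = -lam  # log P(obs | z=0) + const
        num = np.where(self.z == 1, np.log(p + 1e-300) + g1, np.log(1 - p + 1e-300) + g0)
        # log-sum-exp normalizer over z' in {0, 1}
        m = np.maximum(g1, g0)
        denom = m + np.log(p * np.exp(g1 - m) + (1 - p) * np.exp(g0 - m))
        return float(np.sum(num - denom))

    def score(self, beta: float = 0.0, p: float | None = None) -> float:
        """Analytic derivative of the retrospective log-likelihood in beta."""
        if p is None:
            p = float(np.mean(self.z))
        lam = self.cumhaz
        g1p = self.delta - lam * np.exp(beta)  # d/dbeta log P(obs | z=1)
        if beta == 0.0:
            w1 = p  # posterior weight of z=1 at the null equals the prior
        else:
            g1 = self.delta * beta - lam * np.exp(beta)
            g0 = -lam
            m = np.maximum(g1, g0)
            w1 = p * np.exp(g1 - m) / (p * np.exp(g1 - m) + (1 - p) * np.exp(g0 - m))
        return float(np.sum(self.z * g1p - w1 * g1p))

    def fit(self) -> DeletionRiskResults:
        """Score test at beta = 0 with the plug-in null MLE p_hat = mean(z)."""
        p_hat = float(np.mean(self.z))
        resid = self.delta - self.cumhaz
        U = float(np.sum((self.z - p_hat) * resid))
        V = float(p_hat * (1.0 - p_hat) * np.sum(resid**2))
        return DeletionRiskResults(
            gene=self.gene, n=self.nobs, carriers=int(np.sum(self.z)),
            U=U, V=V, model=self,
        )


@dataclass
class GenomewideResults:
    """Per-gene score tests over a carrier matrix, plus skipped genes."""

    results: list
    skipped: list  # (gene, reason)
    deletion_count: dict

    _TABLE_COLUMNS = (
        "gene", "n", "carriers", "carrier_freq", "allele_freq", "deletion_count",
        "U", "V", "chisq", "p_value", "rr", "rr_ci_low", "rr_ci_high", "q_value",
    )

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            lo, hi = r.rr_ci95
            rows.append(
                {
                    "gene": r.gene, "n": r.n, "carriers": r.carriers,
                    "carrier_freq": r.carrier_freq,
                    "allele_freq": r.carriers / (2 * r.n),
                    "deletion_count": self.deletion_count.get(r.gene, r.carriers),
                    "U": r.U, "V": r.V, "chisq": r.chisq, "p_value": r.pvalue,
                    "rr": r.rr, "rr_ci_low": lo, "rr_ci_high": hi,
                    "q_value": np.nan,
                }
            )
        return pd.DataFrame(rows, columns=list(self._TABLE_COLUMNS))

    def with_qvalues(self, count_threshold: int = 4, alpha: float = 0.05) -> pd.DataFrame:
        return discrete_fdr(self.table, count_threshold=count_threshold, alpha=alpha)

    def summary(self, top: int = 10) -> str:
        df = self.table.sort_values("p_value").head(top)
        lines = [
            f"Genome-wide deletion association: {len(self.results)} genes tested, "
            f"{len(self.skipped)} skipped",
            df.to_string(index=False,
                         columns=["gene", "carriers", "carrier_freq", "p_value", "rr"],
                         float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)

    def plot_pvalues(self, ax=None):
        """Uniform QQ plot of the per-gene P-values (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = np.sort(self.table["p_value"].to_numpy())
        expected = (np.arange(1, p.size + 1) - 0.5) / p.size
        ax.plot(-np.log10(expected), -np.log10(p), "o", ms=4)
        lim = max(1.0, -np.log10(expected[0]))
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("expected -log10 P")
        ax.set_ylabel("observed -log10 P")
        return ax


def run_genomewide(matrix, outcomes: pd.DataFrame, incidence: IncidenceModel) -> GenomewideResults:
    """One score test per gene with >= 1 carrier; 0-carrier genes are skipped.

    Results are returned in deterministic (column) gene order and are
    invariant under permutation of the sample rows.
    """
    missing = sorted(set(matrix.samples) - set(outcomes["sample"]))
    if missing:
        raise ValidationError(f"samples without outcomes: {missing[:10]}")
    outcomes = outcomes.set_index("sample").loc[matrix.samples].reset_index()
    results, skipped = [], []
    counts = matrix.deletion_count
    for gene in matrix.genes:
        z = matrix.z[gene]
        if int(z.sum()) == 0:
            skipped.append((gene, "no_carriers"))
            continue
        model = DeletionRiskModel.from_dataframe(outcomes, z, incidence, gene=gene)
        results.append(model.fit())
    return GenomewideResults(
        results=results, skipped=skipped,
        deletion_count={g: int(counts[g]) for g in matrix.genes},
    )


def discrete_fdr(table: pd.DataFrame, count_threshold: int = 4, alpha: float = 0.05) -> pd.DataFrame:
    """Discrete-statistic FDR: count filtering then Benjamini-Hochberg.

    Genes whose total deletion count is below ``count_threshold`` cannot
    reach small P-values with a discrete statistic and are excluded from the
    multiplicity correction (q-value missing, ``filtered`` flag set);
    step-up BH q-values are computed on the retained set only.
    """
    out = table.copy()
    retained = out["deletion_count"] >= count_threshold
    out["filtered"] = ~retained
    out["q_value"] = np.nan
    if retained.any():
        p = out.loc[retained, "p_value"].to_numpy()
        q = multipletests(p, alpha=alpha, method="fdr_bh")[1]
        out.loc[retained, "q_value"] = q
    return out
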