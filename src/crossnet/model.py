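"""Statsmodels-style model objects over the cross-network analysis.

Two fitted-model surfaces are exposed:

* :class:`StmPainModel` — the index-on-pain linear model
  (index = beta0 + beta1 * PL + eps) fitted by OLS; its results object
  carries the coefficient estimates, their standard errors, R² and the
  two-sided slope test, plus a text ``summary()``.

* :class:`CrossNetworkModel` — the whole cohort analysis: per-subject FC
  matrices, network-level FCS, striatum indices, the 21 Bonferroni-corrected
  group comparisons, and the patient pain regression; fitted in one
  ``fit()`` call from cleaned regional time series plus subject metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectivity import (
    CrossNetworkFCS,
    cross_network_matrix,
    pearson_fc_matrix,
    stm_fcs_index,
)
from .extraction import RegionTimeSeriesSet
from .inference import (
    GroupTestResult,
    RegressionResult,
    SubjectRecord,
    bonferroni_adjust,
    group_summary,
    rank_group_test,
)
from .networks import NetworkDefinition, load_network_table


class StmPainModel:
    """Linear model of the striatum connectivity index against pain score.

    Parameters
    ----------
    index, pain
        Paired observations; entries with a missing value in either array
        are dropped (their identifiers, if given, are reported as excluded).
    subject_ids
        Optional identifiers aligned with the observations.
    """

    def __init__(self, index, pain, subject_ids=None):
        index = np.asarray(index, dtype=float)
        pain = np.asarray(pain, dtype=float)
        if index.shape != pain.shape:
            raise ValueError("index and pain must have equal length")
        ids = (
            [str(s) for s in subject_ids]
            if subject_ids is not None
            else [f"s{i}" for i in range(index.size)]
        )
        keep = np.isfinite(index) & np.isfinite(pain)
        self.excluded = tuple(ids[i] for i in np.flatnonzero(~keep))
        self.index = index[keep]
        self.pain = pain[keep]
        self.subject_ids = [ids[i] for i in np.flatnonzero(keep)]
        if self.index.size < 3:
            raise ValueError("need at least 3 complete observations")
        if np.ptp(self.pain) == 0:
            raise ValueError("pain scores have zero variance")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        index_col: str = "stm_index",
        pain_col: str = "vas_pain",
        id_col: str = "subject_id",
    ) -> "StmPainModel":
        ids = df[id_col] if id_col in df.columns else None
        return cls(
            df[index_col].to_numpy(float), df[pain_col].to_numpy(float), ids
        )

    @classmethod
    def from_records(cls, records: list[SubjectRecord]) -> "StmPainModel":
        return cls(
            [np.nan if r.stm_index is None else r.stm_index for r in records],
            [np.nan if r.vas_pain is None else r.vas_pain for r in records],
            [r.subject_id for r in records],
        )

    def fit(self) -> "StmPainResults":
        ols = sm.OLS(self.index, sm.add_constant(self.pain)).fit()
        return StmPainResults(self, ols)


class StmPainResults:
    """Fitted index-on-pain model: estimates, uncertainty, diagnostics."""

    def __init__(self, model: StmPainModel, ols_results):
        self.model = model
        self._ols = ols_results

    @property
    def params(self) -> np.ndarray:
        """(beta0, beta1)."""
        return np.asarray(self._ols.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._ols.bse)

    @property
    def beta0(self) -> float:
        return float(self._ols.params[0])

    @property
    def beta1(self) -> float:
        return float(self._ols.params[1])

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    @property
    def slope_pvalue(self) -> float:
        return float(self._ols.pvalues[1])

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.asarray(self._ols.conf_int(alpha))

    def predict(self, pain) -> np.ndarray:
        pain = np.asarray(pain, dtype=float)
        return self.beta0 + self.beta1 * pain

    def as_regression_result(self) -> RegressionResult:
        return RegressionResult(
            beta0=self.beta0,
            beta1=self.beta1,
            r_squared=self.rsquared,
            p_value=self.slope_pvalue,
            n=self.nobs,
            excluded=self.model.excluded,
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Striatum index ~ pain score (OLS)",
            "=" * 48,
            f"n observations      {self.nobs}",
            f"excluded (missing)  {list(self.model.excluded) or 'none'}",
            f"beta0 (intercept)   {self.beta0:+.4f}  SE {self.bse[0]:.4f}",
            f"beta1 (pain slope)  {self.beta1:+.4f}  SE {self.bse[1]:.4f}",
            f"  95% CI            [{ci[1, 0]:+.4f}, {ci[1, 1]:+.4f}]",
            f"R-squared           {self.rsquared:.4f}",
            f"slope p (2-sided)   {self.slope_pvalue:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of index vs pain with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.pain, self.model.index, color="0.3")
        xs = np.linspace(self.model.pain.min(), self.model.pain.max(), 50)
        ax.plot(xs, self.predict(xs), color="crimson")
        ax.set_xlabel("pain score (VAS)")
        ax.set_ylabel("striatum connectivity index")
        return ax


class CrossNetworkModel:
    """Cohort-level cross-network connectivity analysis.

    Built from per-subject cleaned regional time series and a metadata table
    (columns subject_id, group in {CN, FBSS}, vas_pain).  ``fit()`` computes
    everything downstream of the time series.
    """

    def __init__(
        self,
        timeseries: list[RegionTimeSeriesSet],
        metadata: pd.DataFrame,
        networks: NetworkDefinition | None = None,
        fisher_average: bool = False,
    ):
        self.networks = networks if networks is not None else load_network_table()
        self.timeseries = list(timeseries)
        self.metadata = metadata.copy()
        self.fisher_average = fisher_average
        meta_ids = set(self.metadata["subject_id"].astype(str))
        ts_ids = [ts.subject_id for ts in self.timeseries]
        missing = [s for s in ts_ids if s not in meta_ids]
        if missing:
            raise ValueError(f"subjects missing from metadata: {missing}")
        if len(set(ts_ids)) != len(ts_ids):
            raise ValueError("duplicate subject ids in time series")

    def fit(self, alpha: float = 0.05) -> "CrossNetworkResults":
        nets = self.networks
        group_of = dict(
            zip(self.metadata["subject_id"].astype(str), self.metadata["group"])
        )
        cn_mats: dict[str, CrossNetworkFCS] = {}
        indices: dict[str, float] = {}
        for ts in self.timeseries:
            fc = pearson_fc_matrix(ts)
            cn = cross_network_matrix(
                fc, nets, ts.subject_id, fisher_average=self.fisher_average
            )
            cn_mats[ts.subject_id] = cn
            indices[ts.subject_id] = stm_fcs_index(cn).value

        # 21 network-pair group comparisons, Bonferroni-corrected as a batch.
        names = nets.names
        pvals: dict[str, tuple[float, float]] = {}
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                va = [
                    cn_mats[s].loc(a, b)
                    for s in cn_mats
                    if group_of[s] == "CN"
                ]
                vb = [
                    cn_mats[s].loc(a, b)
                    for s in cn_mats
                    if group_of[s] == "FBSS"
                ]
                pvals[f"{a}-{b}"] = rank_group_test(va, vb)
        comparisons = bonferroni_adjust(pvals, alpha=alpha)

        records = []
        for row in self.metadata.itertuples(index=False):
            sid = str(row.subject_id)
            pain = getattr(row, "vas_pain", None)
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=str(row.group),
                    vas_pain=None if pain is None or pd.isna(pain) else float(pain),
                    stm_index=indices.get(sid),
                )
            )
        patient_records = [r for r in records if r.group == "FBSS"]
        regression = None
        complete = [
            r
            for r in patient_records
            if r.stm_index is not None and r.vas_pain is not None
        ]
        if len(complete) >= 3 and np.ptp([r.vas_pain for r in complete]) > 0:
            regression = StmPainModel.from_records(patient_records).fit()
        return CrossNetworkResults(
            self, cn_mats, records, comparisons, regression, alpha
        )


class CrossNetworkResults:
    """Everything the cohort analysis produced, with a text summary."""

    def __init__(self, model, cross_network, records, comparisons, regression, alpha):
        self.model = model
        self.cross_network: dict[str, CrossNetworkFCS] = cross_network
        self.records: list[SubjectRecord] = records
        self.comparisons: list[GroupTestResult] = comparisons
        self.regression: StmPainResults | None = regression
        self.alpha = alpha

    @property
    def indices(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "vas_pain": r.vas_pain,
                    "stm_index": r.stm_index,
                }
                for r in self.records
            ]
        )

    def group_summary(self) -> dict[str, dict[str, float]]:
        return group_summary([r for r in self.records if r.stm_index is not None])

    def group_mean_matrix(self, group: str) -> pd.DataFrame:
        """Mean 7x7 network FCS matrix over subjects of one group."""
        mats = [
            cn.values
            for sid, cn in self.cross_network.items()
            if any(r.subject_id == sid and r.group == group for r in self.records)
        ]
        if not mats:
            raise ValueError(f"no subjects in group {group!r}")
        names = self.model.networks.names
        return pd.DataFrame(np.mean(mats, axis=0), index=names, columns=names)

    def significant_comparisons(self) -> list[GroupTestResult]:
        return [c for c in self.comparisons if c.significant]

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": c.label,
                    "statistic": c.statistic,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "m": c.m,
                    "significant": c.significant,
                }
                for c in self.comparisons
            ]
        )

    def summary(self) -> str:
        gs = self.group_summary()
        lines = ["Cross-network connectivity analysis", "=" * 48]
        for g, s in gs.items():
            lines.append(
                f"{g}: n={s['n']}  index mean {s['mean']:.4f}  SD {s['sd']:.4f}"
            )
        sig = self.significant_comparisons()
        lines.append(
            f"group comparisons: {len(self.comparisons)} network pairs, "
            f"{len(sig)} Bonferroni-significant at alpha={self.alpha}"
        )
        for c in sorted(sig, key=lambda c: c.p_adjusted):
            lines.append(f"  {c.label}: p_adj = {c.p_adjusted:.4g}")
        if self.regression is not None:
            lines.append("")
            lines.append(self.regression.summary())
        return "\n".join(lines)
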