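"""Functional-connectivity matrices and connectivity-strength summaries.

Functional connectivity (FC) between two regions is the Pearson correlation
of their BOLD time series.  Connectivity strength (FCS) summarises a set of
region pairs by the plain arithmetic mean of their correlations:

* within-network FCS averages the n(n-1)/2 unordered pairs inside one
  network (15 pairs for the six-region striatum network);
* cross-network FCS averages all |A|x|B| pairs between two disjoint
  networks;
* the striatum (STM) connectivity index is the mean of the six cross-network
  FCS values between STM and the other six networks — the per-subject scalar
  regressed on pain scores downstream.

Correlations are averaged signed and untransformed by default; pass
``fisher_average=True`` to average Fisher-z values and back-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import RegionTimeSeriesSet
from .networks import NETWORK_NAMES, NetworkDefinition


@dataclass
class FCMatrix:
    """Symmetric region-pair Pearson correlation matrix.

    The diagonal is a self-connection, not a measurement, and is excluded
    from every average.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        off = v[~np.eye(len(self.labels), dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.values = v
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, rows: list[str], cols: list[str]) -> np.ndarray:
        ri = [self._index[r] for r in rows]
        ci = [self._index[c] for c in cols]
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class CrossNetworkFCS:
    """7x7 network-level FCS matrix for one subject.

    Off-diagonal entry (A, B) is the cross-network FCS between networks A and
    B; the diagonal holds within-network FCS.
    """

    subject_id: str
    networks: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.networks)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match network count")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("cross-network FCS matrix must be symmetric")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        i, j = self.networks.index(a), self.networks.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.networks, columns=self.networks)


@dataclass(frozen=True)
class StmIndex:
    """Per-subject striatum connectivity index: mean of the six STM-to-other
    cross-network FCS values."""

    subject_id: str
    value: float


def pearson_fc_matrix(ts: RegionTimeSeriesSet) -> FCMatrix:
    """Pairwise Pearson correlations between all regional time series."""
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = data.std(axis=0)
    dead = [ts.labels[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance regions: {dead}")
    r = np.corrcoef(data, rowvar=False)
    # Clamp tiny numerical overshoot beyond +/-1.
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return FCMatrix(list(ts.labels), r)


def _mean_fc(vals: np.ndarray, fisher_average: bool) -> float:
    if fisher_average:
        return float(np.tanh(np.mean(fisher_z(vals))))
    return float(vals.mean())


def within_network_fcs(
    fc: FCMatrix, net: list[str], fisher_average: bool = False
) -> float:
    """Mean correlation over the n(n-1)/2 unordered pairs inside a network."""
    n = len(net)
    if n < 2:
        raise ValueError("within-network FCS needs at least 2 regions")
    sub = fc.submatrix(net, net)
    iu = np.triu_indices(n, k=1)
    return _mean_fc(sub[iu], fisher_average)


def cross_network_fcs(
    fc: FCMatrix, net_a: list[str], net_b: list[str], fisher_average: bool = False
) -> float:
    """Mean correlation over all |A|x|B| pairs between two disjoint networks."""
    if not net_a or not net_b:
        raise ValueError("both networks must be non-empty")
    overlap = set(net_a) & set(net_b)
    if overlap:
        raise ValueError(f"networks overlap: {sorted(overlap)}")
    return _mean_fc(fc.submatrix(net_a, net_b).ravel(), fisher_average)


def cross_network_matrix(
    fc: FCMatrix,
    nets: NetworkDefinition,
    subject_id: str = "subject",
    fisher_average: bool = False,
) -> CrossNetworkFCS:
    """Assemble the 7x7 network-level FCS matrix for one subject."""
    names = nets.names
    m = np.empty((len(names), len(names)))
    for i, a in enumerate(names):
        m[i, i] = within_network_fcs(fc, nets[a], fisher_average)
        for j in range(i + 1, len(names)):
            v = cross_network_fcs(fc, nets[a], nets[names[j]], fisher_average)
            m[i, j] = m[j, i] = v
    return CrossNetworkFCS(subject_id, names, m)


def stm_fcs_index(cn: CrossNetworkFCS, network: str = "STM") -> StmIndex:
    """Average the six cross-network FCS entries between STM and the rest.

    The within-STM (diagonal) entry is excluded.
    """
    if network not in cn.networks:
        raise ValueError(f"network {network!r} not present")
    i = cn.networks.index(network)
    row = np.delete(cn.values[i], i)
    if row.size != len(NETWORK_NAMES) - 1:
        raise ValueError("expected six cross-network entries")
    if not np.all(np.isfinite(row)):
        raise ValueError("missing cross-network FCS entry")
    return StmIndex(cn.subject_id, float(row.mean()))


def fisher_z(cc, clip: float = 1e-7):
    """Fisher variance-stabilising transform m = artanh(r) = 0.5*ln((1+r)/(1-r)).

    Values at exactly +/-1 are clipped to +/-(1 - clip) so the transform stays
    finite; the function is odd and strictly increasing.
    """
    arr = np.asarray(cc, dtype=float)
    clipped = np.clip(arr, -1.0 + clip, 1.0 - clip)
    out = np.arctanh(clipped)
    return float(out) if np.isscalar(cc) or arr.ndim == 0 else out


def subject_cross_network_table(
    ts_sets: list[RegionTimeSeriesSet], nets: NetworkDefinition
) -> pd.DataFrame:
    """Long-format table of network-pair FCS values, one row per subject/pair.

    Columns: subject_id, net_a, net_b, fcs (net_a == net_b rows hold the
    within-network value).  Convenience wrapper used by the group-inference
    layer.
    """
    rows = []
    for ts in ts_sets:
        cn = cross_network_matrix(pearson_fc_matrix(ts), nets, ts.subject_id)
        for i, a in enumerate(cn.networks):
            for j in range(i, len(cn.networks)):
                rows.append(
                    {
                        "subject_id": ts.subject_id,
                        "net_a": a,
                        "net_b": cn.networks[j],
                        "fcs": cn.values[i, j],
                    }
                )
    return pd.DataFrame(rows)
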