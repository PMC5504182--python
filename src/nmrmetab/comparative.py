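"""Cross-model and cross-metabolite structure: SUS-plots, Venn partitions,
Pearson correlation networks and STOCSY.

A shared-and-unique-structures (SUS) analysis scatters the per-feature
predictive-score correlations Corr(tp, X) of two OPLS-DA models that share
the same reference class: features significant in both models fall on the
diagonals (shared effects, sign agreement -> positive diagonal), features
significant in exactly one hug an axis (unique effects).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from matplotlib import colormaps

from .chemometrics import OPLSDAResults
from .containers import FeatureMatrix, SpectraSet

__all__ = [
    "sus_plot",
    "venn_categorize",
    "correlation_network",
    "filter_network_by_sus",
    "network_edge_table",
    "stocsy",
]

SUS_CATEGORIES = (
    "shared-positive",
    "shared-negative",
    "unique-A",
    "unique-B",
    "not-significant",
)


def sus_plot(
    model_a: OPLSDAResults,
    model_b: OPLSDAResults,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-feature (corr_A, corr_B) pairs with shared/unique categories.

    Both models must be fitted on the same feature labels with the same
    reference class.  A feature is significant in a model when
    ``|corr| >= threshold``; shared features carry the sign-agreement
    diagonal, unique features are significant in exactly one model.  The
    ``diagonal_distance`` column (|corr_A - corr_B|) is reported for
    plotting only and does not affect the categories.
    """
    if list(model_a.feature_names) != list(model_b.feature_names):
        raise ValueError("models were fitted on different feature labels")
    if model_a.reference_class != model_b.reference_class:
        raise ValueError(
            f"models have different reference classes: "
            f"{model_a.reference_class!r} vs {model_b.reference_class!r}"
        )
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ca, cb = model_a.corr, model_b.corr
    sig_a, sig_b = np.abs(ca) >= threshold, np.abs(cb) >= threshold
    categories = []
    for sa, sb, a, b in zip(sig_a, sig_b, ca, cb):
        if sa and sb:
            categories.append(
                "shared-positive" if np.sign(a) == np.sign(b) else "shared-negative"
            )
        elif sa:
            categories.append("unique-A")
        elif sb:
            categories.append("unique-B")
        else:
            categories.append("not-significant")
    df = pd.DataFrame(
        {
            "corr_A": ca,
            "corr_B": cb,
            "category": categories,
            "diagonal_distance": np.abs(ca - cb),
        },
        index=list(model_a.feature_names),
    )
    df.attrs["threshold"] = threshold
    df.attrs["reference_class"] = model_a.reference_class
    df.attrs["class_A"] = model_a.positive_class
    df.attrs["class_B"] = model_b.positive_class
    return df


def venn_categorize(sus: pd.DataFrame) -> dict:
    """Partition significant features into A-only / B-only / shared sets.

    The shared set is annotated with the (sign_A, sign_B) pair per feature.
    """
    a_only = set(sus.index[sus["category"] == "unique-A"])
    b_only = set(sus.index[sus["category"] == "unique-B"])
    shared = {
        feat: (int(np.sign(row["corr_A"])), int(np.sign(row["corr_B"])))
        for feat, row in sus.iterrows()
        if row["category"].startswith("shared")
    }
    return {"A_only": a_only, "B_only": b_only, "shared": shared}


def _edge_color(r: float) -> str:
    """Map r in [-1, 1] onto a bluish-to-reddish diverging scale (hex)."""
    rgba = colormaps["coolwarm"]((r + 1.0) / 2.0)
    return "#%02x%02x%02x" % tuple(int(round(255 * v)) for v in rgba[:3])


def correlation_network(
    fm: FeatureMatrix,
    group: str | None = None,
    threshold: float = 0.6,
) -> nx.Graph:
    """Pearson correlation network of features within one group.

    Nodes are all features; edges join pairs with ``|r| > threshold`` and
    carry ``r``, a display ``width`` proportional to |r| and a diverging
    ``color`` mapped on [-1, 1].  Zero-variance features stay as isolated
    nodes.
    """
    values = fm.group_values(group) if group is not None else fm.values
    if values.shape[0] < 4:
        raise ValueError("need at least 4 samples for a correlation network")
    X = values.to_numpy(dtype=float)
    names = list(values.columns)
    sd = X.std(axis=0, ddof=1)
    G = nx.Graph()
    G.add_nodes_from(names)
    G.graph["threshold"] = threshold
    G.graph["group"] = group
    ok = np.nonzero(sd > 0)[0]
    if ok.size >= 2:
        R = np.corrcoef(X[:, ok], rowvar=False)
        for ii in range(ok.size):
            for jj in range(ii + 1, ok.size):
                r = float(R[ii, jj])
                if abs(r) > threshold:
                    G.add_edge(
                        names[ok[ii]],
                        names[ok[jj]],
                        r=r,
                        width=abs(r),
                        color=_edge_color(r),
                    )
    return G


def filter_network_by_sus(
    net: nx.Graph,
    sus: pd.DataFrame,
    categories: tuple[str, ...] = (
        "shared-positive",
        "shared-negative",
        "unique-A",
        "unique-B",
    ),
) -> nx.Graph:
    """Induced subgraph on SUS-significant features, with direction flags.

    Nodes keep a ``direction`` attribute ('increased'/'decreased' relative to
    the shared reference class) taken from the sign of the model correlation
    in which the feature is significant (model A first).
    """
    unknown = [f for f in sus.index if f not in net.nodes]
    if unknown:
        raise ValueError(f"SUS features not in network: {unknown[:5]}")
    keep = [f for f in sus.index if sus.loc[f, "category"] in categories]
    sub = net.subgraph(keep).copy()
    thr = sus.attrs.get("threshold", 0.5)
    for feat in sub.nodes:
        row = sus.loc[feat]
        c = row["corr_A"] if abs(row["corr_A"]) >= thr else row["corr_B"]
        sub.nodes[feat]["direction"] = "increased" if c > 0 else "decreased"
    return sub


def network_edge_table(net: nx.Graph) -> pd.DataFrame:
    """Edge list (node_a, node_b, r) for text export."""
    rows = [(u, v, d["r"]) for u, v, d in net.edges(data=True)]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r"])


def stocsy(
    data: FeatureMatrix | SpectraSet,
    driver,
) -> pd.DataFrame:
    """Statistical total correlation spectroscopy from one driver resonance.

    Correlates the driver feature's intensity across samples with every
    feature (or every spectral point when given raw spectra); peaks of the
    same molecule correlate near 1, which is how assignments are confirmed.
    ``driver`` is a feature label / column index (FeatureMatrix) or a ppm
    value (SpectraSet; the nearest grid point is used).

    Returns a table with ``ppm`` (when available), ``r`` and ``cov`` aligned
    to the feature axis.
    """
    if isinstance(data, SpectraSet):
        X = data.intensities
        ppm = data.ppm
        names = [f"{v:.4f}" for v in ppm]
        j = int(np.argmin(np.abs(ppm - float(driver))))
    else:
        X = data.array()
        ppm = data.feature_ppm
        names = list(data.feature_names)
        j = names.index(driver) if not isinstance(driver, (int, np.integer)) else int(driver)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples for STOCSY")
    d = X[:, j]
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance driver")
    dc = d - d.mean()
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    cov = dc @ Xc / (n - 1)
    denom = dc.std(ddof=1) * X.std(axis=0, ddof=1)
    r = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
    return pd.DataFrame(
        {
            "feature": names,
            "ppm": ppm if ppm is not None else np.full(len(names), np.nan),
            "r": np.clip(r, -1.0, 1.0),
            "cov": cov,
        }
    )
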