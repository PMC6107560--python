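"""Basic plotting helper for association networks."""

from __future__ import annotations

import networkx as nx
import pandas as pd


def plot_network(sri: pd.DataFrame, birds: pd.DataFrame | None = None,
                 ax=None, threshold: float = 0.0, seed: int = 0):
    """Spring-layout drawing of one SRI matrix; edge width tracks strength.

    Fathers are drawn darker than offspring when ``birds`` metadata is given.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 6))
    G = nx.Graph()
    G.add_nodes_from(sri.index)
    for i, bi in enumerate(sri.index):
        for bj in sri.columns[i + 1:]:
            w = float(sri.loc[bi, bj])
            if w > threshold:
                G.add_edge(bi, bj, weight=w)
    pos = nx.spring_layout(G, seed=seed, weight="weight")
    widths = [3.0 * G[u][v]["weight"] for u, v in G.edges]
    colors = "lightsteelblue"
    if birds is not None:
        role = birds.set_index("bird_id")["role"]
        colors = [
            "black" if role.get(n) == "father" else "lightsteelblue" for n in G.nodes
        ]
    nx.draw_networkx(G, pos=pos, ax=ax, width=widths, node_color=colors,
                     node_size=220, font_size=6)
    ax.set_axis_off()
    return ax
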