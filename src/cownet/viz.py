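"""Minimal sociogram plotting helper."""

from __future__ import annotations

from .network import DailyNetwork


def plot_sociogram(net: DailyNetwork, ax=None, seed: int = 0):
    """Draw a network as a sociogram (spring layout); returns the axes."""
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.from_numpy_array(net.adjacency)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=seed)
    nx.draw_networkx(
        g,
        pos=pos,
        ax=ax,
        node_size=60,
        width=0.5,
        with_labels=False,
        node_color="tab:blue",
        edge_color="gray",
    )
    title = f"day {net.day}" if net.day is not None else ""
    if net.area:
        title = f"{net.area} {title}".strip()
    ax.set_title(title)
    ax.set_axis_off()
    return ax
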