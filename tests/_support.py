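"""Shared test helpers."""

import numpy as np


def make_uniform_flow(grid, u=0.0, v=0.0, t_max=7 * 86400.0,
                      open_boundaries=True):
    """Hand-built flow archive with a constant uniform current."""
    from reefconnect.hydrodynamics import FlowField

    times = np.arange(0.0, t_max + 1, 3600.0)
    nt = len(times)
    ny, nx = grid.n_y, grid.n_x
    return FlowField(
        times=times,
        eta=np.zeros((nt, ny, nx), np.float32),
        u=np.full((nt, ny, nx + 1), u, np.float32),
        v=np.full((nt, ny + 1, nx), v, np.float32),
        grid=grid,
        open_boundaries=open_boundaries,
    )
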