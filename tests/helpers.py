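import numpy as np

from soma_spt.tracking import Trajectory


def make_trajectory(times, xy, gap=None, particle_id=0):
    """Assemble a Trajectory from raw time/position arrays."""
    times = np.asarray(times, float)
    xy = np.asarray(xy, float)
    n = len(times)
    return Trajectory(
        particle_id=particle_id,
        frames=np.arange(n),
        times=times,
        xy=xy,
        photons=np.full(n, np.nan),
        gap=np.zeros(n, bool) if gap is None else np.asarray(gap, bool),
    )
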