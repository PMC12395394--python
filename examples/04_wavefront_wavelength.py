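"""The refractory-to-active ratio Delta sets the emitted wavelength.

On a larger ordered tissue (936 cells) with a single seeded junction,
tau_act = 2 and kL = 0.5, waves are emitted periodically from the source;
the spacing between concentric activity rings grows with
Delta = tau_ref/tau_act, and for large Delta re-emission stops and only a
solitary pulse remains.
"""

import numpy as np

import vertexpulse as vp
from vertexpulse import observables

base = vp.make_hexagonal_tissue(936)
mech = vp.MechParams(k_l=0.5, dt=0.05)
print(f"tissue: {base.n_cells} cells, box "
      f"{base.box.lx:.1f} x {base.box.ly:.1f}")

for delta in (0.1, 0.25, 0.4, 1.0):
    excit = vp.ExcitParams(eps_on=0.1, tau_act=2.0, tau_ref=2.0 * delta,
                           gamma0=0.5)
    t = base.copy()
    vp.seed_activation(t, "single", excit)
    j = int(np.flatnonzero(t.state == vp.ACTIVE)[0])
    origin = t.edge_midpoints()[j]
    res = vp.run_simulation(t, mech, excit, t_end=25.0,
                            snapshot_interval=1.0, copy=False)
    rec = observables.record_from_result(res)
    late = [s for s in res.snapshots if s[0] >= 15.0]
    wl = observables.measure_wavelength(late, origin,
                                        bin_width=vp.HEX_EDGE_LENGTH)
    print(f"Delta={delta:4}: {rec.label:5s}  wavelength = "
          f"{'undefined' if wl is None else f'{wl:.2f}'}  (units sqrt(A0))")

# Wavelength = front speed x re-emission period; a longer refractory tail
# delays re-activation at the source, stretching the rings apart until,
# past a critical Delta, the source never re-fires.
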