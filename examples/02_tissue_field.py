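"""Solve the layered-retina extracellular field for a 200 μm disc electrode.

The admittance method turns the voxelized tissue into a resistive network
and solves it for a unit (1 μA) drive; potentials for any stimulus follow
by scaling.  The printout shows the on-axis potential decaying with depth
into the retina — the spatial gradient that polarizes a bipolar cell.
"""

import numpy as np

from retisim import field as fld

stack = fld.default_layer_stack()
electrode = fld.Electrode(diameter=200.0, current=1.0)
system = fld.assemble_system(stack, electrode, voxel=10.0,
                             extent=(600.0, 600.0, 450.0), z_fraction_below=1 / 3)
grid = fld.solve_field(system)
print(f"grid {grid.phi.shape}, residual {grid.residual:.1e}, "
      f"boundary current {fld.boundary_current(system, grid):.6f} μA")

depths = np.array([20.0, 40.0, 60.0, 80.0, 105.0, 150.0])
ve = fld.sample_potentials(grid, [[0.0, 0.0, z] for z in depths])
print("on-axis extracellular potential (per 1 μA injected):")
for z, v in zip(depths, ve):
    print(f"  z = {z:5.0f} μm   Ve = {v:7.4f} mV")
print("a cathodic −100 μA pulse multiplies these by −100: the axon terminals"
      "\n(~60 μm) sit in a steeper, more negative field than the soma (~105 μm)")
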