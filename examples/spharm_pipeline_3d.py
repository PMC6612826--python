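"""Robust spherical parameterization and SPHARM descriptors in 3D.

Builds a neuron-like 3D voxel cell (a hard case: long thin neurites),
runs topology fixation, graph-diameter pole selection and constrained
area-equalization, fits spherical harmonic descriptors at several maximum
orders and prints the reconstruction error of each.
"""

import cellshape as cs

vol = cs.generate_snl_3d(cs.SNLParams(n_neurites=2, seed=7))
print(f"volume {vol.shape}, {int(vol.voxels.sum())} foreground voxels")

mesh, mapping, diag = cs.parameterize_robust(
    vol, cs.RPDMOptions(working_order=31))
print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces; "
      f"closing kernel {diag.applied_kernel}; "
      f"{diag.iterations} optimizer iterations; "
      f"max area ratio {diag.max_area_ratio:.2f}")
print(f"success check at L = {diag.working_order}: reconstruction error "
      f"{diag.reconstruction_error:.2f} px (failure threshold 100 px)")

for L in (4, 8, 15, 31):
    desc = cs.fit_descriptor(mesh, mapping, L)
    rec = cs.reconstruct_surface(desc, 2562)
    err = cs.hausdorff_distance(mesh.vertices, rec.vertices)
    print(f"  L = {L:2d}: {(L + 1) ** 2:4d} coefficients/coordinate, "
          f"reconstruction error {err:6.2f} px")

print("Higher orders capture finer surface detail; the neurites demand "
      "much higher L than a smooth blob would.")
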