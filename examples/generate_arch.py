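"""Generate a synthetic labeled maxillary arch and save it as PLY.

Prints the per-class vertex census: void (gingiva + background) and the
rugae patch dominate, with a few dozen vertices per tooth crown —
the same kind of class imbalance intraoral scans show.
"""

import numpy as np

from dentalseg import ArchParams, generate_arch, write_landmarks, write_ply

mesh, landmarks = generate_arch(ArchParams(n_teeth=14, seed=1))
write_ply(mesh, "arch_texture.ply")
write_ply(mesh, "arch_labels.ply", encode_labels_as_colors=True)
write_landmarks(landmarks, "arch_landmarks.txt")

print(f"vertices: {mesh.n_vertices}, faces: {mesh.n_faces}")
print(f"{'class':<28}{'vertices':>9}")
for lid in mesh.present_labels():
    n = int((mesh.label == lid).sum())
    print(f"{mesh.scheme[int(lid)].name:<28}{n:>9}")
print("\nlandmarks (mm):")
print(np.round(landmarks.all_points, 2))
print("\nwrote arch_texture.ply, arch_labels.ply, arch_landmarks.txt")
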