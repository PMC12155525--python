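"""Train the reduced SegNet on a small rendered set and score held-out views.

A demonstration-scale run: two synthetic scans rendered from a narrow
anterior viewing sector (a standardized acquisition protocol), 64x64
images, 40 epochs.  Loss should fall steadily; held-out mIoU after this
short run stays modest — the acceptance-scale run (250 epochs) pushes it
past 0.6.  Expect a few minutes on one CPU.
"""

import numpy as np

from dentalseg import ArchParams, LightingConfig, generate_arch, render_pair
from dentalseg.nn import ImagePair, SegNetConfig, TrainConfig, build_segnet, train
from dentalseg.render import sample_camera_poses


def scan_views(scan_seed, pose_seed, n_views, size=64):
    mesh, _ = generate_arch(ArchParams(seed=scan_seed, mesh_resolution=2000))
    lo, hi = mesh.vertices.min(0), mesh.vertices.max(0)
    center, radius = (lo + hi) / 2, float(np.linalg.norm(hi - lo)) / 2
    poses = sample_camera_poses(
        n_views, pose_seed, 1.7 * radius, center, image_size=size,
        elevation_range_deg=(55, 80), azimuth_range_deg=(-30, 30),
        roll_range_deg=(-9, 9),
    )
    return [
        ImagePair(
            render_pair(mesh, p, LightingConfig("ambient")).texture_image
            .transpose(2, 0, 1).astype(np.float32) / 255.0,
            render_pair(mesh, p).label_ids,
            scan_id=scan_seed,
        )
        for p in poses
    ]


train_set = scan_views(101, 1, 10) + scan_views(102, 2, 10)
val_set = scan_views(103, 3, 4)  # a scan the model never sees

model = build_segnet(
    SegNetConfig(encoder_layers=4, n_classes=28, input_size=64,
                 attention_placement="end"),
    seed=0,
)
print(f"model parameters: {model.n_parameters}")
model, hist = train(
    model, train_set,
    TrainConfig(epochs=40, batch_size=1, learning_rate=1e-4, decay=0.995, seed=0),
    val_set=val_set,
)
for e in range(0, 40, 10):
    print(f"epoch {e:3d}: train loss {hist['train_loss'][e]:.4f}  "
          f"val mIoU {hist['val_miou'][e]:.3f}")
print(f"final:     train loss {hist['train_loss'][-1]:.4f}  "
      f"val mIoU {hist['val_miou'][-1]:.3f}")
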