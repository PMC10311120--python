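"""Generate one synthetic correlative scene and write its images.

Builds a ground-truth scene (nuclei + heterochromatin puncta + a known
modality misalignment), renders the EM and fluorescence channels, and saves
TIFFs plus the ground-truth transform XML.  The printed transform is the true
EM-frame -> fluorescence-frame similarity that registration must undo.
"""

from pathlib import Path

from clemalign import (
    SceneParams,
    TransformRecord,
    render_em,
    render_fluorescence,
    sample_scene,
    write_image,
    write_overlay,
    write_transform_xml,
)

out = Path("scene_out")
out.mkdir(exist_ok=True)

scene = sample_scene(SceneParams(seed=7))
em = render_em(scene)
chrom_aligned = render_fluorescence(scene, apply_misalignment=False)
chrom_measured = render_fluorescence(scene, apply_misalignment=True)

write_image(em, out / "em.tif")
write_image(chrom_aligned, out / "chromatin_aligned.tif")
write_image(chrom_measured, out / "chromatin_measured.tif")
write_overlay(em, [chrom_aligned], out / "overlay_aligned.png")
write_transform_xml(
    TransformRecord.from_transform(scene.true_transform, scene.params.pixel_size_nm),
    out / "true_transform.xml",
)

t = scene.true_transform
print(f"scene: {len(scene.puncta)} puncta in {len(scene.nuclei)} nuclei, "
      f"{scene.params.pixel_size_nm} nm/px")
print(f"true misalignment: theta={t.theta_deg:+.2f} deg, scale={t.scale:.4f}, "
      f"shift=({t.tx_px:+.1f}, {t.ty_px:+.1f}) px")
print(f"outputs in {out}/")
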