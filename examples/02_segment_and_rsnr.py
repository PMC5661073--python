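"""Template-based LV segmentation and the RSNR statistic on one subject.

Builds a male template from a few simulated normal subjects (spatial
normalization to a reference + voxelwise averaging + Otsu mask), then runs
the fully automatic pipeline on a TVD-like phantom: each acquisition is
registered to the template and the template LV mask is carried back through
the inverse transformation.
"""

from dataclasses import replace

from rsnrspect import (
    CohortPopulation,
    Grid,
    PhantomSpec,
    build_templates,
    classify_tvd,
    dice,
    make_lv_phantom,
    run_pipeline,
    simulate_template_normals,
)

grid = Grid((48, 48, 48), (4.0, 4.0, 4.0))
population = CohortPopulation(base_spec=PhantomSpec(grid=grid))

print("building the male template from 6 normal rest studies ...")
normals = simulate_template_normals(6, population, seed=11)
templates = build_templates({"M": normals["M"]})
print(f"template LV mask: {templates['M'].lv_mask.n_voxels} voxels")

subject = make_lv_phantom(
    replace(population.base_spec, stress_scale=0.55, seed=99), label="TVD"
)
record = run_pipeline(subject.rest, subject.stress, templates["M"], sex="M")

print(f"rest:   mean {record.snr_rest.mean:6.2f}  SD {record.snr_rest.sd:5.2f}  "
      f"SNR {record.snr_rest.snr:.2f}  ({record.snr_rest.n_voxels} voxels)")
print(f"stress: mean {record.snr_stress.mean:6.2f}  SD {record.snr_stress.sd:5.2f}  "
      f"SNR {record.snr_stress.snr:.2f}  ({record.snr_stress.n_voxels} voxels)")
print(f"RSNR = {record.rsnr:.3f} -> {classify_tvd(record.rsnr)} at the 0.94 cutoff")
print(f"segmentation Dice vs ground truth: rest "
      f"{dice(record.mask_rest, subject.truth_mask_rest):.2f}, stress "
      f"{dice(record.mask_stress, subject.truth_mask_stress):.2f}")
print("-> an RSNR below 0.94 flags globally reduced stress uptake (balanced ischemia).")
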