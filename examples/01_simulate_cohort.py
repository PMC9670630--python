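"""Simulate a paired CSF + plasma cohort measured on three platforms.

Builds the default 18 AD / 18 control cohort with planted co-expression
modules and prints what each platform sees.
"""
from fluidnet import simulate_cohort
from fluidnet.model import Fluid, Platform

cohort = simulate_cohort(seed=1)

print("subjects:", len(cohort.traits.subjects),
      dict(cohort.traits.group_labels().value_counts()))
for (platform, fluid), matrix in cohort.matrices.items():
    print(f"{platform.value:9s} {fluid.value:7s} {matrix.shape[0]:3d} samples"
          f" x {matrix.shape[1]:3d} assays  ({matrix.scale.value})")

truth = cohort.truth
n_modules = truth.module_of_protein.max()
sizes = truth.module_of_protein[truth.module_of_protein > 0].value_counts()
print(f"\nplanted modules: {n_modules} (sizes {sorted(sizes)})")
noise = truth.noise_assays[(Platform.SOMASCAN, Fluid.CSF)]
print(f"pure-noise SomaScan CSF assays: {len(noise)} "
      "(emulating aptamer background in CSF)")
# The three platforms measure overlapping protein sets; the module factor
# scores also drive the clinical traits (tau, amyloid, MoCA), so module
# eigenproteins recovered downstream should correlate with them.
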