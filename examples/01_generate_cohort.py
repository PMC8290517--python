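"""Generate a phantom glioma cohort and inspect its clinical table.

Each subject gets three aligned MRI-like channels (T1WI, T2WI, CE-T1WI), an
ellipsoidal tumor mask, and clinical covariates. The two classes (1p/19q
codeleted vs non-codeleted) differ only in intratumoral texture: codeleted
tumors are sampled from a rougher random field.
"""

from gliomics import CohortSpec, clinical_table, generate_cohort

# desk-scale version of the study cohort (full size: 65 + 92 at 64 mm grids)
spec = CohortSpec(n_codel=6, n_noncodel=8, image_shape=(48, 48, 48), seed=7)
records = generate_cohort(spec)

table = clinical_table(records)
print(table.to_string(index=False))
print()
print(f"subjects: {len(records)}  codeleted: {table.label_1p19q.sum()}")
print(f"age mean +/- sd: {table.age.mean():.1f} +/- {table.age.std():.1f} years")
print("tumor volumes (cm^3):", [round(r.mask.volume_cm3, 1) for r in records])
# The label counts follow the spec exactly; ages are drawn from one law for
# both classes, so age carries no class signal. Volumes follow a truncated
# normal capped by what fits in the image grid.
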