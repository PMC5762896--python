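"""Clinical reference-cohort comparisons and headline rates.

Expands the bundled count tables of the 109-patient HER2+ breast
conservation cohort into per-patient records, compares the no-re-excision
and re-excision groups variable by variable (chi-square, or Fisher's exact
for sparse 2x2 tables), and prints the derived rates the pipeline reports.
"""

from bcsradiomics import clinical
from bcsradiomics.stats import cohort_summary

records = clinical.records()
summary = cohort_summary(
    records, categorical=["DCIS", "ER", "PR", "localization", "multifocal_mri"]
)

print(f"cohort: {summary.group_sizes[0]} no re-excision, "
      f"{summary.group_sizes[1]} re-excision\n")
for var, info in summary.categorical.items():
    print(f"{var:15s} p = {info['p']:.3f} ({info['test']})")
    for i, cat in enumerate(info["categories"]):
        print(f"    {cat:12s} {info['counts'][0][i]:3d} ({info['percent'][0][cat]:3d}%)"
              f"  vs  {info['counts'][1][i]:3d} ({info['percent'][1][cat]:3d}%)")

print("\nderived rates:")
print(f"  re-excision after initial BCS: {clinical.reexcision_rate():.1f}%")
print(f"  residual carcinoma at re-excision: {clinical.residual_carcinoma_rate():.1f}%")
print(f"  mastectomy at first re-excision: "
      f"{clinical.mastectomy_at_first_reexcision_rate():.1f}%")
for k, v in clinical.multifocal_rates().items():
    print(f"  multifocal/multicentric ({k}): {v:.1f}%")
print("\nAssociations with DCIS, hormone-receptor status and multifocality "
      "mirror why irregular, extensive tumors are harder to excise cleanly.")
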