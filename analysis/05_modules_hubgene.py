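"""Gene-module convergence: which mutation converges across module systems?

Builds PPI-based modules (size-bounded Louvain communities of the panel
network) and treatment-based modules (from the paradigm annotation),
scores each module's post-treatment any-mutation status as a pCR
discriminator, and intersects the modules with AUC > 0.65 to obtain the
hub gene set.
"""

from common import RESULTS, load_cohort
from ctpet.io import read_ppi_edges, read_treatment_annotation
from ctpet.modules import (
    assign_treatment_modules,
    build_ppi_modules,
    gene_status_table,
    hub_genes,
    module_auc,
    module_report,
)
from ctpet.pipeline import label_cohort, quantify_cohort

variants, samples, paths = load_cohort()
quant = quantify_cohort(variants, samples)
labels = label_cohort(samples)
pcr = {l.sample_id: l.is_pcr for l in labels}
panel = [
    line.strip() for line in paths["panel"].read_text().splitlines()
    if line.strip()
]
status = gene_status_table(quant, "post", panel=panel)

modules = build_ppi_modules(read_ppi_edges(paths["ppi_edges"]), panel, seed=1)
modules += assign_treatment_modules(
    read_treatment_annotation(paths["treatment_annotation"]), panel
)
modules = [module_auc(m, status, pcr) for m in modules]
hub = hub_genes(modules)

report = module_report(modules)
report.to_csv(RESULTS / "05_modules.tsv", sep="\t", index=False,
              float_format="%.4f")
print(report.to_string(index=False,
                       float_format=lambda v: f"{v:.3f}"))
qualifying = report[report.qualifies]["module_id"].tolist()
print(f"\nqualifying modules (AUC > 0.65): {qualifying}")
print(f"hub gene(s) = intersection of qualifying modules: {sorted(hub)}")
(RESULTS / "05_hub_genes.txt").write_text("\n".join(sorted(hub)) + "\n")
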