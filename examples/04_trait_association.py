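"""Module-trait association, candidate genes, and hub export.

Runs the whole pipeline on a synthetic study, correlates module
eigengenes with metabolite traits (sucrose, malic acid, beta-ionone,
gamma-decalactone), and selects trait-coupled candidate genes
(|r| > 0.91) and intramodular hubs.
"""

from flavornet import PipelineConfig, SyntheticConfig, run_pipeline, simulate_dataset

ds = simulate_dataset(SyntheticConfig(seed=42))
res = run_pipeline(ds.counts, ds.traits, PipelineConfig(seed=42, outdir="scratch/example04"))

print("module-trait correlations (rows: modules):")
print(res["module_trait_r"].round(3))
print("\n... and their p-values:")
print(res["module_trait_p"].map(lambda p: f"{p:.0e}"))
# Sucrose and malic acid load the same module with opposite signs
# (sugars accumulate while acids are consumed); |r| near 0.95-0.98 at
# n = 9 gives p around 1e-5, the regime where a module counts as
# trait-associated (p < 0.001).

print("\nsignificant modules:", res["significant_modules"])
print("candidate genes (|r| > 0.91):", len(res["candidates"]))
print("hubs:", list(res["hubs"].index[res["hubs"].is_hub]))
print("network edges exported:", len(res["edges"]))
# candidates.tsv, hubs.tsv and edges.tsv (Cytoscape-ready) are written
# under the output directory together with a manifest.json.
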