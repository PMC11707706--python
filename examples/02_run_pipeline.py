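"""Run the full decoupling analysis on a simulated scene and read the summary.

Stages: May-September filter -> 1 km village-radius filter -> era assignment
(L5 1990-2011, L8 2013-2024) -> per-season mean/variance metrics -> nearest
abandoned-land-use reference pairing -> detrended OLS decoupling tests ->
sign-quadrant classification -> landscape summary + GeoJSON/plot outputs.
"""
import gardentrends as gt

scene = gt.generate_scene(gt.SimulationConfig(n_gardens=400, n_references=100,
                                              n_villages=6, seed=11))
result = gt.run_pipeline(gt.PipelineConfig(out_dir="pipeline_out"),
                         centroids=scene.centroids,
                         observations=scene.observations)

table = result.summary
print(f"analysis universe: {table.n_gardens_universe} garden centroids")
for era, es in table.eras.items():
    print(f"\n{era}: {es.n_gardens_analyzed} gardens with fittable series")
    print(f"  both trends significant:     {es.pct_both_significant:6.2f}%")
    print(f"  at least one significant:    {es.pct_at_least_one:6.2f}%")
    for label, share in es.cluster_shares.items():
        print(f"  {label:<22s} {share:6.2f}% of both-significant gardens")
print(f"\ncombined (either era): {table.n_qualifying} gardens "
      f"= {table.pct_qualifying_of_all:.2f}% of the universe")
print("\nA both-significant garden has greening AND diversification trends that "
      "remain significant after the nearest reference's trends are removed -- "
      "evidence that its dynamics are decoupled from the local background.")
print("Outputs written to pipeline_out/: summary.{csv,json}, cluster_shares.csv, "
      "classified_{E1,E2,combined}.geojson, quadrant_scatter.png, manifest.json")
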