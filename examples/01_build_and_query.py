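"""Build a correlation store from a synthetic cohort and query the hub.

Simulates a 105-sample cohort with one hub gene driving 30 responders at
population correlation 0.8, computes all pairwise Pearson correlations, and
lists the hub's most significant partners with raw/Bonferroni/BH values.
"""

import tempfile
from pathlib import Path

import corrbrowser as cb

spec = cb.SimulationSpec(n_samples=105, n_features=300,
                         hubs=(cb.HubSpec("HUB01", 30, 0.8),),
                         pcr_block=None, rng_seed=0)
matrix, truth = cb.simulate_cohort(spec)

with tempfile.TemporaryDirectory() as tmp:
    store = cb.build_store(matrix, Path(tmp) / "store.h5")
    print(f"store: {store.n_features} features, {store.n_pairs} pairs "
          f"(= F(F-1)/2)")

    print("\ntop 5 partners of HUB01 (p ascending):")
    print("partner        r        p_raw        p_bonf       q_bh")
    for rec in store.top_neighbors("HUB01", 5):
        partner = store.partner_of(rec, "HUB01")
        print(f"{partner:12s}  {rec.r:.4f}  {rec.p_raw:.3e}  "
              f"{rec.p_bonferroni:.3e}  {rec.q_bh:.3e}")

    planted = set(truth.responders["HUB01"])
    top30 = {store.partner_of(r, "HUB01") for r in store.top_neighbors("HUB01", 30)}
    print(f"\nplanted responders recovered in top 30: "
          f"{len(top30 & planted)}/30")
# Planted correlations of 0.8 at n = 105 dominate the null background, so the
# top of the list should be (almost) exactly the 30 planted responders.
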