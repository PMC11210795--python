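"""Track issue resolution across assessment rounds.

Round one runs on an extract where a site's nephrology specialty codes were
lost in ETL; the site fixes its extraction and round two re-executes the
same checks.  The comparison marks the specialty issue "improvement" and
reports the metric before and after.
"""

from ssdqa import (AnomalySpec, SimConfig, compare_rounds, generate_network,
                   inject_anomaly, load_catalog, run_dq)

clean = generate_network(SimConfig(n_sites=5, patients_per_site=200, seed=5))
site = clean.site_ids()[2]
broken, _ = inject_anomaly(clean, AnomalySpec("drop_specialty", site))

checks = load_catalog("DQ1")
before = run_dq(broken, "DQ1")   # ETL bug present
after = run_dq(clean, "DQ1")     # site fixed its extraction

comp = compare_rounds(before.issues, before.results, after.results, checks)
print(f"{len(comp)} issues tracked, {int(comp['resolved'].sum())} resolved")
fix = comp[(comp["site_id"] == site) & (comp["element"] == "nephrology_specialty")]
print(fix.to_string(index=False))
# metric_before is the nephrology-visit completeness (0 while broken);
# metric_after recovers and the status flips to "improvement".
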