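"""Call SNaP (presence/absence) markers from systematic array-call failure.

A 288 bp deletion removes an array probe site: every carrier yields a
"failed" call at that marker.  Ordinary QC throws the marker away; SNaP
calling re-reads the failure pattern as a dominant marker, validated by the
1:1 segregation expected within each DH subfamily.
"""

from svqtl import (
    GeneticMap,
    SVLocusSpec,
    call_snap,
    inject_call_failures,
    make_dh_population,
    qc_filter,
    simulate_founders,
)

gmap = GeneticMap.dense({"A02": 2_000_000}, spacing_bp=50_000)
sv = SVLocusSpec("SV288", "A02", 900_000, 900_288, "DEL", carriers=["P2", "P4", "P6"])
founders = simulate_founders(7, gmap, [sv], seed=10)
pop = make_dh_population(founders, seed=11)

raw = inject_call_failures(pop.genotypes, founders.sv_records(), pop.sv_genotypes)
fail = raw.marker_fail_rate()
print("markers with failed calls:", fail[fail > 0].round(3).to_dict())

filtered, report = qc_filter(raw)
print(f"\nQC: {filtered.n_markers}/{raw.n_markers} markers pass "
      f"({(report['kind'] == 'marker').sum()} excluded)")

snaps, recoded = call_snap(raw)
for s in snaps:
    print(f"\nSNaP candidate {s.marker}: accepted={s.accepted}")
    for fam, (presence, absence) in s.counts.items():
        p = s.pvalues.get(fam)
        tag = f"p={p:.3f}" if p is not None else "monomorphic"
        print(f"  {fam}: {presence}:{absence} ({tag})")
print(f"\n{recoded.n_markers} accepted SNaP marker(s) recoded as dominant calls;")
print("p >= 0.05 in every polymorphic subfamily means the failure pattern")
print("segregates 1:1, as a real deleted probe site should in a DH cross.")
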