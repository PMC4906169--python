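"""Immuno-gold periphery statistic along a Golgi long axis.

Compares a uniform axial distribution of gold particles with a centrally
concentrated one — the signature of cargo confined to the middle of the
cisternal stack — using the relative-distance-from-centre statistic.
"""

from golgiring import (
    compare_groups,
    generate_gold_particles,
    gold_relative_distance,
    summarize_distribution,
)

L = 1200.0  # Golgi length, nm
uniform = generate_gold_particles(200, L, "uniform", seed=1)
central = generate_gold_particles(200, L, "central", concentration=4.0, seed=2)

for name, tbl in (("uniform", uniform), ("central", central)):
    d = gold_relative_distance(tbl.position_nm.to_numpy(), golgi_length=L)
    s = summarize_distribution(d.relative_distances)
    print(f"{name:8s} median d_rel = {s.median:.3f} "
          f"(IQR {s.q25:.3f}-{s.q75:.3f}, n = {s.n})")

cmp = compare_groups(
    gold_relative_distance(uniform.position_nm.to_numpy(), golgi_length=L).relative_distances,
    gold_relative_distance(central.position_nm.to_numpy(), golgi_length=L).relative_distances,
)
print(f"t = {cmp.statistic:.2f} ({cmp.method}), two-tailed p = {cmp.p_two_tailed:.2e}")

# d_rel = |distance from axis midpoint| / axis length, in [0, 0.5].
# A uniform distribution has mean 0.25; a centrally confined cargo pulls the
# median down, and the F-test-gated t-test quantifies the difference.
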