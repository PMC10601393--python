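# Eight-scenario study design for Caucasian sweet-chestnut microsatellite data.
# Five sampled lineages: I Lesser Caucasus, II Greater Caucasus, III West+East
# Greater Caucasus, IV East Greater Caucasus, V Europe. Events are read
# backward in time: "split t : A B -> C" merges A and B into C at time t
# (forward: A and B diverged from C); "admix t : T = S1 * ra + S2" derives T
# from S1 (proportion ra) and S2 at time t.

[lineages]
I   : ne=NeI   sample=62
II  : ne=NeII  sample=72
III : ne=NeIII sample=65
IV  : ne=NeIV  sample=40
V   : ne=NeV   sample=27

[loci]
count = 9
ancestral_size = 20
allowed_states = 40
motif = 2

# Scenario 1: first split of I/IV/V at t2, II diverges from I at t1,
# III is an admixture of II (proportion ra) and IV at ta.
[scenario 1]
split t2 : IV V -> I
split t1 : II -> I
admix ta : III = II * ra + IV

# Scenario 2: as Scenario 1 but II never diverged from I after t2 —
# II is a t2 lineage and the admixture is the only later event.
[scenario 2]
split t2 : II IV V -> I
admix ta : III = II * ra + IV

# Scenario 3: all lineages from a single divergence event at t1.
[scenario 3]
split t1 : II III IV V -> I

# Scenario 4: west-east structure — II diverged from I and IV from III at
# the same depth t1, after a deeper three-way split of I, III and Europe (V).
[scenario 4]
split t2 : III V -> I
split t1 : II -> I
split t1 : IV -> III

# Scenarios 5-7: nested bifurcating hierarchies over the same groups,
# differing in the parent of III and in the order of the two inner splits.
[scenario 5]
split t2 : IV V -> I
split t1 : II -> I
split ta : III -> II

[scenario 6]
split t2 : IV V -> I
split t1 : II -> I
split ta : III -> IV

[scenario 7]
split t2 : IV V -> I
split t1 : III -> IV
split ta : II -> I

# Scenario 8: lineage IV ancestral to all Caucasian lineages; Europe (V)
# diverges first.
[scenario 8]
split t2 : V -> IV
split t1 : I III -> IV
split ta : II -> I

[priors]
NeI     = uniform 100 30000
NeII    = uniform 100 30000
NeIII   = uniform 100 30000
NeIV    = uniform 100 30000
NeV     = uniform 100 30000
t1      = uniform 10 10000
t2      = uniform 10 10000
ta      = uniform 10 10000
ra      = uniform 0.001 0.999
mu_mean = uniform 1e-5 1e-3
p_mean  = uniform 0.1 0.3
mu_shape = 2
p_shape  = 2

[constraints]
ta < t1 < t2
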