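# orchardnet

Orchard phylogenetic networks as trees with horizontal arcs: cherry
picking, HGT-consistent labellings, and certified rNNI rearrangement
paths.

## The problem

Rooted phylogenetic networks extend phylogenetic trees with
*reticulations* — nodes with two or more incoming arcs that model
hybridization, recombination, or horizontal gene transfer (HGT).
*Orchard* networks are the networks that can be reduced to a single
leaf by repeatedly picking **cherries** (two leaves with a common
parent; delete one) and **reticulated cherries** (a leaf whose
reticulation parent shares a parent with another leaf; delete the
reticulation arc).  They arise naturally when networks are built by
repeatedly joining the most closely related taxa, and they are strictly
more general than tree-child networks.

This package implements two results about that class and the machinery
around them, for people who work with network search spaces (Bayesian
or maximum-likelihood network inference, rearrangement heuristics) or
who need a solid toolbox for cherry-picking sequences:

1. **Characterization.**  A binary network is orchard **iff** it admits
   an *HGT-consistent labelling*: a map `t` from nodes to numbers with

   - (P1) `t(u) ≤ t(v)` on every arc `(u, v)`, equality only into a
     reticulation,
   - (P2) every internal node has a child with a strictly larger label,
   - (P3) every reticulation is contemporaneous (`t` equal) with
     exactly one of its parents.

   Arcs with equal endpoint labels are *horizontal* — instantaneous
   lateral transfers.  Deleting them and suppressing degree-two nodes
   leaves a *base tree*, so orchard networks are exactly the networks
   drawable as a tree with added horizontal arcs (and in particular are
   tree-based).  The obstruction is the *crown*, a cyclic alternating
   structure `{(u_i, v_i), (u_i, v_{i+1})}` that forces
   `t(u_1) < t(u_2) < … < t(u_1)`.  A non-binary network is orchard iff
   some *binary resolution* of it admits such a labelling.

2. **Connectivity.**  The space of binary orchard networks on `n`
   leaves with `k` reticulations is connected under rNNI moves (local
   rearrangements `(p,x,c) --e--> (z,w)` with `{p,c} ∩ {z,w} ≠ ∅`),
   with diameter at most

   `4kn + n⌈log₂ n⌉ + 2k + 6n − 8`.

   The proof is constructive and implemented as such: both networks are
   driven to a canonical form (all reticulations stacked *neatly at the
   top*, an anchor leaf below the head of the lowest horizontal arc,
   the remaining taxa in a sorted pendant caterpillar) and the two
   half-paths are concatenated.  Every intermediate network carries a
   verified HGT-consistent labelling as a machine-checkable
   certificate, so the path never leaves orchard space.  Paths are
   upper-bound constructions, not shortest paths.

## Worked example

The bundled 13-taxon gamma-proteobacteria network with two HGT events
is reconstructed from its 14-pair cherry-picking sequence:

```python
from orchardnet import synth, is_orchard, labelling_from_sequence
from orchardnet import horizontal_arcs, base_tree, write_enewick

net, seq = synth.gamma_proteobacteria_network()
print(write_enewick(net))
# (((((((((1,2),(3,4)),(5,6)),(10)#H1),((7,8),(9)#H2)),#H2),#H1),((11,12),13)));

ok, greedy = is_orchard(net)
print(ok, len(greedy))          # True 14   (minimal: n + k - 1 = 13 + 2 - 1)

t = labelling_from_sequence(net, seq)
print(len(horizontal_arcs(net, t)))   # 2    (one horizontal arc per HGT event)
print(write_enewick(base_tree(net, t)))
# ((((((((1,2),(3,4)),(5,6)),(7,8)),9),10),((11,12),13)));
```

The greedy orchard test reduces the network to a single leaf in 14
steps (the minimum for 13 leaves and 2 reticulations); the constructive
labelling marks exactly the two transfer arcs as horizontal, and
deleting them yields the base tree on all 13 taxa.

A certified rearrangement path between two random orchard networks:

```python
from orchardnet import synth, orchard_path, diameter_bound

n1 = synth.random_orchard(synth.GeneratorConfig(n=5, k=2, seed=1))
n2 = synth.random_orchard(synth.GeneratorConfig(n=5, k=2, seed=2))
path = orchard_path(n1, n2)
print(len(path), diameter_bound(5, 2))   # 18 81
nets = path.replay(verify=True)          # validates every step + certificate
```

The path of 18 rNNI moves stays well below the diameter bound of 81;
`replay(verify=True)` re-applies every move and re-checks each
network's labelling certificate.

## Command line

```bash
orchardnet is-orchard net.enwk          # orchardness + reduction sequence
orchardnet label net.enwk               # HGT-consistent labelling (or exit 1)
orchardnet basetree net.enwk            # base tree after deleting horizontal arcs
orchardnet reduce net.enwk seq.txt      # apply a cherry-picking sequence
orchardnet reconstruct "(a, b)(c, b)"   # rebuild a network from a sequence
orchardnet path --from A.enwk --to B.enwk --out path.json --verify
orchardnet bound -n 13 -k 2             # diameter bound (230)
orchardnet generate --n 6 --k 2 --seed 7 --kind orchard
orchardnet resolve poly.enwk            # non-binary: orchard binary resolution
```

Networks are exchanged as extended Newick (eNewick) with `#H` hybrid
tags; all reports are JSON; exit codes are 0 (success), 1 (domain
error, e.g. no labelling exists), 2 (usage).

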