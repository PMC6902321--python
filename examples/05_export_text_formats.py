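"""Round-trip the simulation through the plain-text interchange formats.

Writes the pedigree, phenotype table, genotype matrix of the genotyped
animals and the sparse A-inverse to whitespace-delimited files, reads them
back, and verifies the round trip.
"""

import tempfile
from pathlib import Path

import numpy as np

import gsvcbias as g
from gsvcbias import io

sim = g.simulate(g.mini_scale(), seed=1)
out = Path(tempfile.mkdtemp())

io.write_pedigree(sim.pedigree, out / "pedigree.txt")
io.write_phenotypes(sim.phenotypes, out / "phenotypes.txt")
geno_idx = np.flatnonzero(sim.pedigree.is_genotyped)
io.write_genotypes(geno_idx, sim.state.marker_genotypes(geno_idx), out / "genotypes.txt")
io.write_sparse_lower(g.a_inverse(sim.pedigree), out / "a_inverse.txt")

ped = io.read_pedigree(out / "pedigree.txt")
ph = io.read_phenotypes(out / "phenotypes.txt")
ids, geno = io.read_genotypes(out / "genotypes.txt")
ainv = io.read_sparse_lower(out / "a_inverse.txt", shape=sim.pedigree.n)

print(f"wrote {out}")
print(f"pedigree rows: {len(ped)}  phenotypes: {len(ph)}  genotypes: {geno.shape}")
print("pedigree round-trip exact:", bool((ped['sire'].to_numpy() - 1 == sim.pedigree.sire).all()))
print("genotype round-trip exact:", bool(np.array_equal(geno, sim.state.marker_genotypes(ids))))
print("A-inverse round-trip max |delta|:",
      float(abs((ainv - g.a_inverse(sim.pedigree)).toarray()).max()))
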