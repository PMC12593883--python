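"""One-off generator for the packaged surrogate consensus library.

Writes src/svatrx/data/sva_consensus.fasta and sva_consensus_regions.tsv.
Architecture (D/E/F): hexamer CCCTCT (6) + alu_like (300) + vntr (15 x 37-mer)
+ sine_r (490, terminal AATAAA).  F1: mast2 (385) + alu_remnant (last 120 bp
of F alu_like) + vntr + sine_r with 6 diagnostic SNVs.

SINE-R motif layout (relative to sine_r start, length 490, signal end 490):
  AAGAAA at [150,156)   weak signal, 17 bp upstream of the 323-hotspot cut (167)
  GTTAAA at [234,240)   G->A creates ATTAAA, 23 bp upstream of the 233-hotspot cut (257)
  AATAAA at [484,490)   canonical signal
Cut positions 167/257 and the two preceding bases are non-A so that truncated
bodies never bleed into the poly-A tail.
"""

import numpy as np
from pathlib import Path

rng = np.random.default_rng(20250901)
BASES = np.array(list("ACGT"))

SINER_LEN = 490
ALU_LEN = 300
MAST2_LEN = 385
VNTR_UNITS = 15
REMNANT_LEN = 120

PROTECTED_REL = set()
for lo, hi in [(150, 156), (234, 240), (484, 490)]:
    PROTECTED_REL.update(range(lo, hi))
# hotspot cut positions and the two bases upstream of each
PROTECTED_REL.update([165, 166, 167, 255, 256, 257])
DIAG_REL = [40, 95, 190, 280, 330, 410]
PROTECTED_REL.update(DIAG_REL)


def rand_seq(n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def scrub(seq, banned=("AATAAA",), protected=()):
    """Remove banned motifs by flipping one unprotected base inside each hit."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for motif in banned:
            i = text.find(motif)
            while i != -1:
                for j in range(i, i + len(motif)):
                    if j not in protected:
                        cur = s[j]
                        s[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
                        changed = True
                        break
                i = text.find(motif, i + 1)
                if changed:
                    break
            if changed:
                break
    return "".join(s)


def mutate(seq, rate, protected=()):
    s = list(seq)
    n_mut = int(round(rate * len(s)))
    positions = [p for p in rng.permutation(len(s)) if p not in protected][:n_mut]
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(len(choices))]
    return "".join(s)


# --- shared building blocks -------------------------------------------------
base_alu = scrub(rand_seq(ALU_LEN, gc=0.55))
mast2 = scrub(rand_seq(MAST2_LEN, gc=0.55))
vntr_unit = scrub(rand_seq(37, gc=0.70))
vntr = vntr_unit * VNTR_UNITS

siner = list(rand_seq(SINER_LEN, gc=0.50))
siner[150:156] = "AAGAAA"
siner[234:240] = "GTTAAA"
siner[484:490] = "AATAAA"
for pos in (165, 166, 167, 255, 256, 257):
    if siner[pos] == "A":
        siner[pos] = "C"
base_siner = scrub("".join(siner), protected=PROTECTED_REL)
assert base_siner[484:490] == "AATAAA" and base_siner[234:240] == "GTTAAA"
assert base_siner[150:156] == "AAGAAA"

# --- per-subfamily alu/sine_r variants --------------------------------------
DIVERGENCE = 0.06
alu = {"F": base_alu}
sr = {"F": base_siner}
for sub in ("D", "E"):
    alu[sub] = scrub(mutate(base_alu, DIVERGENCE))
    sr[sub] = scrub(mutate(base_siner, DIVERGENCE, protected=PROTECTED_REL),
                    protected=PROTECTED_REL)
    assert sr[sub][484:490] == "AATAAA" and sr[sub][234:240] == "GTTAAA"
    assert sr[sub][150:156] == "AAGAAA"

# F1 sine_r: F sine_r with diagnostic substitutions
sr_f1 = list(base_siner)
diag_rows = []
for rel in DIAG_REL:
    f_allele = sr_f1[rel]
    f1_allele = {"A": "G", "G": "A", "C": "T", "T": "C"}[f_allele]
    sr_f1[rel] = f1_allele
    diag_rows.append((rel, f_allele, f1_allele))
sr_f1 = scrub("".join(sr_f1), protected=PROTECTED_REL)

HEX = "CCCTCT"
seqs = {}
regions = {}
for sub in ("D", "E", "F"):
    seqs[sub] = HEX + alu[sub] + vntr + sr[sub]
    a0 = 6
    v0 = a0 + ALU_LEN
    s0 = v0 + len(vntr)
    regions[sub] = [("hexamer", 0, 6), ("alu_like", a0, v0), ("vntr", v0, s0),
                    ("sine_r", s0, s0 + SINER_LEN)]

remnant = alu["F"][ALU_LEN - REMNANT_LEN:]
seqs["F1"] = mast2 + remnant + vntr + sr_f1
m0 = MAST2_LEN
r1 = m0 + REMNANT_LEN
v1 = r1 + len(vntr)
regions["F1"] = [("mast2", 0, m0), ("alu_remnant", m0, r1), ("vntr", r1, v1),
                 ("sine_r", v1, v1 + SINER_LEN)]
assert m0 == 385

for sub, seq in seqs.items():
    # only one AATAAA, at the very end
    assert seq.count("AATAAA") == 1 and seq.endswith("AATAAA"), sub

# identical downstream of the junction apart from diagnostics
offset = len(seqs["F"]) - len(seqs["F1"])
shared_f1 = seqs["F1"][385:]
shared_f = seqs["F"][385 + offset:]
diff = [i for i, (a, b) in enumerate(zip(shared_f, shared_f1)) if a != b]
sr_start_f1 = regions["F1"][3][1]
assert diff == [sr_start_f1 - 385 + rel for rel in DIAG_REL], diff

out = Path(__file__).resolve().parents[1] / "src" / "svatrx" / "data"
out.mkdir(parents=True, exist_ok=True)
with open(out / "sva_consensus.fasta", "w") as fh:
    for sub in ("D", "E", "F", "F1"):
        fh.write(f">{sub}\n")
        s = seqs[sub]
        for i in range(0, len(s), 70):
            fh.write(s[i:i + 70] + "\n")

rows = ["subfamily\tfeature\tname\tstart\tend\tnote"]
for sub in ("D", "E", "F", "F1"):
    for name, s, e in [(n, s, e) for n, s, e in regions[sub]]:
        rows.append(f"{sub}\tregion\t{name}\t{s}\t{e}\t.")
    L = len(seqs[sub])
    rows.append(f"{sub}\tsignal\tpolya\t{L - 6}\t{L}\tAATAAA")
rows.append("F1\tjunction\tmast2\t385\t385\t.")
siner_start_f1 = regions["F1"][3][1]
for rel, fa, f1a in diag_rows:
    pos = siner_start_f1 + rel
    rows.append(f"F1\tdiagnostic\tdv{rel}\t{pos}\t{pos + 1}\tF={fa};F1={f1a}")
with open(out / "sva_consensus_regions.tsv", "w") as fh:
    fh.write("\n".join(rows) + "\n")
print("wrote", out)
for sub in seqs:
    print(sub, len(seqs[sub]))
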