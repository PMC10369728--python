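#!/usr/bin/env python
"""Simulate the study inputs: labelled training peptides and a metagenome.

Writes, under results/simulated/:
  acp.fasta / amp_neg.fasta / random.fasta  -- 225 peptides per class
  reads.fastq                               -- 1,000 reads, 5 planted ACPs
  truth.tsv                                 -- planted ground truth

The ACP class raises K/L/A/I and lowers D/E relative to uniform (cationic,
hydrophobic character); the AMP-negative class is cationic but not
hydrophobic; the random class is uniform. Plants are embedded on both
strands at recorded frames/coordinates with zero substitution errors.
"""

import argparse
from pathlib import Path

from pepmine import synthetic_data as sd
from pepmine.read_qc import RawRead
from pepmine.seqio import write_sequences

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    profiles = [sd.acp_profile(), sd.amp_negative_profile(), sd.random_profile()]
    sets = sd.simulate_training_sets(profiles, 225, seed=args.seed)
    for label, peps in sets.items():
        path = OUT / f"{label.lower()}.fasta"
        write_sequences([RawRead(f"{label}_{i:03d}", p)
                         for i, p in enumerate(peps)], path, fmt="fasta")
        print(f"{label}: {len(peps)} peptides -> {path}")

    reads, truth = sd.simulate_metagenome(sd.SimulationConfig(seed=args.seed))
    write_sequences(reads, OUT / "reads.fastq")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"metagenome: {len(reads)} reads, {len(truth)} plants "
          f"(lengths {sorted(truth.peptide_sequence.str.len())})")


if __name__ == "__main__":
    main()
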