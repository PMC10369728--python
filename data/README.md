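# data/

Place the Pfam homeodomain profile here to enable the PF00046 integration
test (`tests/test_acceptance.py::TestHomeodomainEnvelope`):

    hmmfetch Pfam-A.hmm PF00046.24 > data/PF00046.hmm

The profile is not redistributed with the package; fetching it requires
network access to Pfam/InterPro.
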