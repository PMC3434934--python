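Place the journal-hosted supplementary species-jurisdiction tables here as
`sd2.csv` (the body/clutch-complete table) and `sd3.csv` (the larger table
without those traits) to enable the published-data reproduction checks in
`tests/test_acceptance.py`. These files are third-party data and are not
redistributed with this repository.
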