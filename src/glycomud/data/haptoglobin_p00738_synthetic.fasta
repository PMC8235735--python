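>HPT_HUMAN_synthetic haptoglobin precursor stand-in; beta-subunit region (162-406) carries the four N-glycosites Asn184/207/211/241 with canonical numbering; signal/alpha region is a synthetic filler preserving length and tryptic boundaries
MSALGAVIALLLWGQLFAVDSGNDVTDIADDGCPKPPEIAHGYVEHSVRYQCKNYYKLRT
EGDGVYTLNDKKQWINKAVGDKDDGCPKPPEIAHGYVEHSVRYQCKNYYKLRTEGDGVYT
LNNEKQWINKAVGDKLPECEALPECEAVCGKPKNPANPVQRILGGHLDAKGSFPWQAKMV
SHHNLTTGATLINEQWLLTTAKNLFLNHSENATAKDIAPTLTLYVGKKQLVEIEKVVLHP
NYSQVDIGLIKLKQKVSVNERVMPICLPSKDYAEVGRVGYVSGWGRNANFKFTDHLKYVM
LPVADQDQCIRHYEGSTVPEKKTPKSPVGVQPILNEHTFCAGMSKYQEDTCYGDAGSAFA
VHDLEEDTWYATGILSFDKSCAVAEYGVYVKVTSIQDWVQKTIAEN
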