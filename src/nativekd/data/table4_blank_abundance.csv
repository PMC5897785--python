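replicate,ab_free
1,71438882
2,80188529
3,70622004
4,94929471
5,61169836
6,65198871
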