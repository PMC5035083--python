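category,gold_neg_reader_neg,gold_neg_reader_pos,gold_pos_reader_neg,gold_pos_reader_pos
red,1857,522,204,2197
yellow,2996,543,465,776
green,3483,159,555,583
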