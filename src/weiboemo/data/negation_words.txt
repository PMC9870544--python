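不
没
没有
未
别
莫
勿
毫不
并不
并非
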