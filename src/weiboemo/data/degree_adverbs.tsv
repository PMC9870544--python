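最	2.0
极其	2.0
非常	1.75
很	1.75
太	1.75
十分	1.75
特别	1.75
更	1.5
更加	1.5
比较	1.5
越来越	1.5
过于	1.5
过分	1.5
稍微	1.2
有点	1.2
有些	1.2
略	1.2
不太	0.5
不够	0.5
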