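word,code,intensity,polarity
高兴,PA,7,1
快乐,PA,9,1
开心,PA,7,1
喜悦,PA,5,1
欢乐,PA,5,1
愉快,PA,5,1
安心,PE,5,1
踏实,PE,3,1
放心,PE,5,1
尊敬,PD,5,1
敬佩,PD,7,1
赞扬,PH,5,1
点赞,PH,5,1
表扬,PH,3,1
相信,PG,5,1
信任,PG,5,1
喜爱,PB,5,1
热爱,PB,7,1
喜欢,PB,5,1
支持,PB,3,1
祝愿,PK,5,1
祝福,PK,5,1
加油,PK,3,1
愤怒,NA,9,2
生气,NA,5,2
恼火,NA,5,2
气愤,NA,7,2
愤慨,NA,7,2
悲伤,NB,7,2
伤心,NB,7,2
难过,NB,5,2
悲痛,NB,9,2
失望,NJ,5,2
绝望,NJ,9,2
沮丧,NJ,5,2
内疚,NH,5,2
惭愧,NH,3,2
思念,PF,5,0
想念,PF,3,0
慌张,NI,5,2
紧张,NI,3,2
心慌,NI,5,2
恐惧,NC,9,2
害怕,NC,7,2
恐慌,NC,7,2
担心,NC,3,2
担忧,NC,5,2
畏惧,NC,5,2
羞愧,NG,3,2
烦闷,ND,5,2
烦躁,ND,5,2
郁闷,ND,5,2
讨厌,NE,5,2
厌恶,NE,7,2
憎恨,NE,9,2
恶心,NE,5,2
谴责,NN,5,2
批评,NN,3,2
指责,NN,5,2
嫉妒,NK,5,2
怀疑,NL,3,2
质疑,NL,3,2
惊讶,PC,5,1
震惊,PC,7,1
吃惊,PC,5,1
惊奇,PC,5,1
意外,PC,3,1
诧异,PC,5,1
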