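日报
晚报
时报
电视台
广播
电台
官方
政府
卫健委
疾控
发布
新闻
网信
委员会
人民网
新华
央视
融媒体
杂志
门户
宣传部
公安
法院
检察院
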