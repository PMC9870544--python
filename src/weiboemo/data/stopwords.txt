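的
了
在
是
我
你
他
她
它
我们
有
和
就
都
而
及
与
着
或
一个
也
还
把
被
让
向
往
这
那
这个
那个
什么
怎么
因为
所以
但是
不过
如果
虽然
吧
吗
呢
啊
呀
于
对
对于
关于
不
没有
很
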