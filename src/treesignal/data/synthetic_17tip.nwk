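(((t1:1.1365124153739476,(t2:0.69132450078873986,(((t3:0.062733655014785006,t4:0.062733655014785006):0.34145127426602317,(t5:0.16387762201408385,t6:0.16387762201408385):0.24030730726672433):0.22035731714220019,t7:0.62454224642300837):0.066782254365731486):0.44518791458520779):0.41680622878985646,(((t8:0.73686168194878721,t9:0.73686168194878721):0.52354379325884537,(t10:0.50230583081844093,(t11:0.13864385307941673,t12:0.13864385307941673):0.3636619777390242):0.75809964438919164):0.0036273076526136538,t13:1.2640327828602462):0.28928586130355788):0.28708413737170385,((t14:0.22568786907279947,t15:0.22568786907279947):0.53361062445064955,(t16:0.47999235953840591,t17:0.47999235953840591):0.27930613398504311):1.0811042880120589);
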